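"""Local mean suppression filtering (LMSF) for background identification.

The filter is a pixel-wise (or sample-wise) nonlinear operator: a value is
replaced by zero when its ratio to the mean of its local neighborhood falls
strictly below a threshold ``theta``; otherwise the original value is kept
untouched.  Local means use *adaptive averaging*: near the borders the window
is clipped to the available samples and the sum is divided by the count of
available samples — no padding of any kind.

Background identification combines the filter across a set of window
half-widths ``N`` (the *cumulative* response): a pixel is background if any
single scale labels it background, equivalently the Boolean product of the
per-scale foreground masks.

All local means are computed with summed-area tables, so the per-pixel cost
is independent of the window size; integer images are accumulated exactly in
``int64``, floating-point images in ``float64``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FilterParams",
    "n_max",
    "local_mean_1d",
    "lmsf_1d",
    "local_mean_2d",
    "lmsf_2d",
    "cumulative_lmsf",
    "select_scales",
    "as_scale_set",
    "DEFAULT_THETA",
    "THETA_RECOMMENDED_RANGE",
]

#: Default threshold; works well whenever foreground/background contrast is
#: not unusually fuzzy.  The recommended operating range is 0.5–1 (values up
#: to ~1.1 are useful for very fuzzy foregrounds).
DEFAULT_THETA = 0.5
THETA_RECOMMENDED_RANGE = (0.5, 1.0)


@dataclass(frozen=True)
class FilterParams:
    """Single-scale filter parameters: threshold ``theta`` and half-window ``n``.

    ``n`` is the half-width of the averaging window: a 1-D window holds
    ``2n + 1`` samples, a 2-D window ``(2n + 1) x (2n + 1)`` pixels.  For an
    analog half-window ``T`` sampled at step ``dt``, ``n ~ round(T / dt)``.
    """

    theta: float = DEFAULT_THETA
    n: int = 1

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")


def n_max(K: int, M: int) -> int:
    """Largest admissible averaging half-window for a ``K x M`` image.

    ``n_max = floor(min(K, M) / 2) - 1``.  Requires ``K, M >= 4`` so the
    bound is at least 1.
    """
    K, M = int(K), int(M)
    if K < 4 or M < 4:
        raise ValueError(
            f"image of shape ({K}, {M}) is too small: no valid half-window "
            "exists below min(K, M)//2 - 1 (need K, M >= 4)"
        )
    return min(K, M) // 2 - 1


# ---------------------------------------------------------------------------
# validation helpers

def _check_n(n: int) -> int:
    if int(n) != n or n < 1:
        raise ValueError(f"half-window n must be a positive integer, got {n!r}")
    return int(n)


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    return theta


def _as_signal(signal, require_nonneg: bool) -> np.ndarray:
    x = np.asarray(signal)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(np.asarray(x, dtype=float))):
        raise ValueError("signal contains non-finite values")
    if require_nonneg and np.any(x < 0):
        raise ValueError("signal intensities must be non-negative")
    return x


def _as_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    K, M = img.shape
    if K < 2 or M < 2:
        raise ValueError(f"image too small: shape ({K}, {M})")
    if not np.all(np.isfinite(np.asarray(img, dtype=float))):
        raise ValueError("image contains non-finite values")
    if np.any(img < 0):
        raise ValueError("image intensities must be non-negative")
    return img


def _acc_dtype(a: np.ndarray):
    # exact accumulation for integer inputs; float64 otherwise
    return np.int64 if np.issubdtype(a.dtype, np.integer) else np.float64


# ---------------------------------------------------------------------------
# adaptive (clipped-window, no-padding) window sums

def _window_sums_1d(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-window sums and available-sample counts for half-width ``n``."""
    K = x.size
    acc = _acc_dtype(x)
    S = np.zeros(K + 1, dtype=acc)
    np.cumsum(x, dtype=acc, out=S[1:])
    idx = np.arange(K)
    lo = np.maximum(idx - n, 0)
    hi = np.minimum(idx + n, K - 1) + 1
    return S[hi] - S[lo], hi - lo


def _window_sums_2d(img: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-window sums and pixel counts over (2n+1)^2 windows.

    Summed-area table with one zero guard row/column; the window is
    intersected with the image domain, so counts vary near the borders.
    """
    K, M = img.shape
    acc = _acc_dtype(img)
    S = np.zeros((K + 1, M + 1), dtype=acc)
    np.cumsum(np.cumsum(img, axis=0, dtype=acc), axis=1, out=S[1:, 1:])
    r = np.arange(K)
    c = np.arange(M)
    r0 = np.maximum(r - n, 0)
    r1 = np.minimum(r + n, K - 1) + 1
    c0 = np.maximum(c - n, 0)
    c1 = np.minimum(c + n, M - 1) + 1
    sums = (
        S[np.ix_(r1, c1)]
        - S[np.ix_(r0, c1)]
        - S[np.ix_(r1, c0)]
        + S[np.ix_(r0, c0)]
    )
    counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return sums, counts


# ---------------------------------------------------------------------------
# local means

def local_mean_1d(signal, n: int) -> np.ndarray:
    """Adaptive local mean of a 1-D signal over windows of ``2n + 1`` samples.

    Interior samples average the full window; near the sequence ends only the
    available samples are averaged (``n + 1`` values at an end point, and so
    on) — no padding.  Output has the input's length; dtype is float64.
    """
    x = _as_signal(signal, require_nonneg=False)
    n = _check_n(n)
    sums, counts = _window_sums_1d(x, n)
    return sums / counts


def local_mean_2d(image, n: int) -> np.ndarray:
    """Adaptive local mean of an image over ``(2n+1) x (2n+1)`` windows.

    The window is clipped to the image domain and the sum divided by the
    count of available pixels.  Adaptive averaging is well defined for any
    window size, so the mean itself accepts any ``n >= 1``; the filter
    entry points enforce the ``n <= n_max`` bound.
    """
    img = _as_image(image)
    n = _check_n(n)
    sums, counts = _window_sums_2d(img, n)
    return sums / counts


# ---------------------------------------------------------------------------
# the filter

def _suppress(x: np.ndarray, sums: np.ndarray, counts: np.ndarray,
              theta: float) -> tuple[np.ndarray, np.ndarray]:
    # Strict "<": ratio exactly equal to theta is foreground.  Compared as
    # value*count < theta*window_sum to avoid division rounding; a zero
    # window sum means every sample in the window is zero (non-negative
    # data), so the pixel itself is zero and is labeled background outright.
    xf = np.asarray(x, dtype=np.float64)
    background = (xf * counts < theta * np.asarray(sums, dtype=np.float64))
    background |= sums == 0
    out = x.copy()
    out[background] = 0
    return out, background


def lmsf_1d(signal, n: int, theta: float = DEFAULT_THETA
            ) -> tuple[np.ndarray, np.ndarray]:
    """Single-scale 1-D filter response and background flags.

    Each output sample is 0 where ``sample / local_mean < theta`` (flag
    True), and exactly the original sample elsewhere.
    """
    x = _as_signal(signal, require_nonneg=True)
    n = _check_n(n)
    theta = _check_theta(theta)
    sums, counts = _window_sums_1d(x, n)
    return _suppress(x, sums, counts, theta)


def lmsf_2d(image, n: int, theta: float = DEFAULT_THETA
            ) -> tuple[np.ndarray, np.ndarray]:
    """Single-scale 2-D filter response and background mask.

    Returns ``(filtered, background)`` where ``filtered`` keeps the input
    dtype with background pixels zeroed (kept pixels bit-identical), and
    ``background`` is a boolean mask (True = background).
    """
    img = _as_image(image)
    n = _check_n(n)
    theta = _check_theta(theta)
    bound = n_max(*img.shape)
    if n > bound:
        raise ValueError(f"n={n} exceeds n_max={bound} for shape {img.shape}")
    sums, counts = _window_sums_2d(img, n)
    return _suppress(img, sums, counts, theta)


# ---------------------------------------------------------------------------
# multi-scale background identification

def as_scale_set(scales: Sequence[int], shape: tuple[int, int] | None = None
                 ) -> tuple[int, ...]:
    """Validate, deduplicate, and sort a set of averaging half-windows.

    If ``shape`` is given, scales exceeding ``n_max`` raise rather than being
    silently clamped, to keep runs reproducible.
    """
    vals = sorted({int(s) for s in scales})
    if len(vals) == 0:
        raise ValueError("scale set must be non-empty")
    if any(int(s) != s for s in np.atleast_1d(list(scales))):
        raise ValueError("scales must be integers")
    if vals[0] < 1:
        raise ValueError(f"scales must be >= 1, got {vals[0]}")
    if shape is not None:
        bound = n_max(*shape)
        if vals[-1] > bound:
            raise ValueError(
                f"scale {vals[-1]} exceeds n_max={bound} for shape {shape}"
            )
    return tuple(vals)


def cumulative_lmsf(image, scales: Sequence[int],
                    theta: float = DEFAULT_THETA
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-scale background identification.

    For every half-window ``n`` in ``scales`` the single-scale filter is
    applied to the *original* image; the cumulative background is the
    pixelwise union of the per-scale backgrounds (the Boolean product of the
    per-scale foregrounds).  Returns ``(filtered, background)`` with the
    cumulative-background pixels of the input zeroed.
    """
    img = _as_image(image)
    theta = _check_theta(theta)
    scale_set = as_scale_set(scales, shape=img.shape)
    background = np.zeros(img.shape, dtype=bool)
    for n in scale_set:
        _, mask = lmsf_2d(img, n, theta)
        background |= mask
    out = img.copy()
    out[background] = 0
    return out, background


def select_scales(max_gap_width_px: int,
                  image_shape: tuple[int, int] | None = None,
                  large_background: bool = False,
                  min_scale: int = 5) -> tuple[int, ...]:
    """Rule-of-thumb scale selection from the maximal background-gap width.

    The largest scale is half the maximal width of the narrow background
    gaps; successive halving (integer floor) adds smaller scales down to
    ``min_scale``.  For images with a large, extended background set
    ``large_background=True``: ``n_max`` of the image is appended so the
    widest windows capture long-range gradual intensity variation, and
    halving-family values above ``n_max`` are dropped.
    """
    max_gap = int(max_gap_width_px)
    min_scale = int(min_scale)
    if max_gap < 1 or min_scale < 1:
        raise ValueError("max_gap_width_px and min_scale must be positive")
    if not large_background and max_gap < 2 * min_scale:
        raise ValueError(
            f"max gap width {max_gap} is below 2*min_scale={2 * min_scale}; "
            "no scale can be selected"
        )
    family = []
    m = max_gap // 2
    while m >= min_scale:
        family.append(m)
        m //= 2
    if large_background:
        if image_shape is None:
            raise ValueError("large_background=True requires image_shape")
        bound = n_max(*image_shape)
        family = [s for s in family if s <= bound]
        family.append(bound)
    if not family:
        raise ValueError("no feasible scales for the given parameters")
    return tuple(sorted(set(family)))
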