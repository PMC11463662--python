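"""Synthetic fluorescence-like fixtures with known ground-truth background.

Generates 1-D test signals (sine-squared, piecewise-constant steps) and 2-D
nuclei-like images: elliptical-to-round Gaussian-profile blobs of varying
brightness on a dim, optionally tilted, noisy background.  Every generator is
fully determined by its seed, so fixtures can be regenerated anywhere instead
of being stored.

Three named presets mirror the practical regimes background identification
has to cope with:

``large-background``
    sparse bright nuclei on an extended dim background,
``large-foreground``
    densely clustered nuclei with only narrow background gaps,
``fuzzy-foreground``
    dim, low-contrast nuclei barely above a noisy elevated background.

Ground truth defines a blob's support as the disk where its Gaussian profile
exceeds ``support_fraction`` (default 10%) of its peak; the true background
mask is the complement of the union of blob supports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "NucleiSceneSpec",
    "GroundTruth",
    "gen_sine_signal",
    "gen_step_signal",
    "gen_nuclei_image",
    "background_f1",
    "PRESETS",
    "preset_filter_params",
    "write_fixture",
]


def gen_sine_signal(num_periods: float, samples_per_period: int) -> np.ndarray:
    """Uniformly sampled sin^2(t) over ``num_periods`` periods (period pi).

    The sampling step is ``pi / samples_per_period``; with an odd
    ``samples_per_period`` a window of that many samples spans exactly one
    period, which makes the interior adaptive local mean exactly 0.5.
    """
    if samples_per_period < 8:
        raise ValueError("samples_per_period must be >= 8")
    if num_periods <= 0:
        raise ValueError("num_periods must be positive")
    K = int(round(num_periods * samples_per_period))
    t = np.arange(K) * (np.pi / samples_per_period)
    return np.sin(t) ** 2


def gen_step_signal(levels, seed: int = 0, noise_sd: float = 0.0) -> np.ndarray:
    """Piecewise-constant signal from ``(value, length)`` segments.

    Optional additive Gaussian noise (sd ``noise_sd``) truncated at zero;
    seed-deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    pieces = []
    for value, length in levels:
        if value < 0:
            raise ValueError(f"level values must be non-negative, got {value}")
        if int(length) != length or length < 1:
            raise ValueError(f"segment lengths must be positive, got {length}")
        pieces.append(np.full(int(length), float(value)))
    if not pieces:
        raise ValueError("levels must be non-empty")
    x = np.concatenate(pieces)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = np.maximum(x + rng.normal(0.0, noise_sd, x.size), 0.0)
    return x


@dataclass(frozen=True)
class NucleiSceneSpec:
    """Parameters of a synthetic nuclei scene.

    Intensities are in arbitrary fluorescence units.  ``clustering`` blends
    blob placement from image-wide uniform (0) to tight clusters (1).
    ``support_fraction`` is the fraction of a blob's peak that defines its
    ground-truth support radius.
    """

    shape: tuple[int, int] = (256, 256)
    n_blobs: int = 40
    radius_range: tuple[float, float] = (6.0, 14.0)
    peak_range: tuple[float, float] = (120.0, 250.0)
    dim_fraction: float = 0.25
    dim_ratio: float = 0.2
    background_offset: float = 4.0
    gradient_amplitude: float = 1.5
    noise_sd: float = 1.5
    clustering: float = 0.0
    seed: int = 0
    support_fraction: float = 0.1

    def __post_init__(self) -> None:
        K, M = self.shape
        if K < 8 or M < 8:
            raise ValueError(f"scene too small: {self.shape}")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid radius range {self.radius_range}")
        if 2 * hi >= min(K, M):
            raise ValueError(
                f"blobs of radius up to {hi} cannot fit a {self.shape} image"
            )
        plo, phi = self.peak_range
        if not (0 < plo <= phi):
            raise ValueError(f"invalid peak range {self.peak_range}")
        if not (0 < self.dim_ratio < 1):
            raise ValueError("dim_ratio must be in (0, 1)")
        if not (0 <= self.dim_fraction <= 1):
            raise ValueError("dim_fraction must be in [0, 1]")
        if self.background_offset < 0 or self.gradient_amplitude < 0:
            raise ValueError("background terms must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.clustering <= 1):
            raise ValueError("clustering must be in [0, 1]")
        if not (0 < self.support_fraction < 1):
            raise ValueError("support_fraction must be in (0, 1)")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """True background mask plus per-blob geometry of a synthetic scene."""

    background: np.ndarray  # bool, True = background
    centers: np.ndarray     # (n_blobs, 2) row/col
    radii: np.ndarray       # (n_blobs,) support radii in px
    peaks: np.ndarray       # (n_blobs,) peak intensities above background

    @property
    def foreground(self) -> np.ndarray:
        return ~self.background


def gen_nuclei_image(spec: NucleiSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a nuclei scene: offset + gradient + Gaussian blobs + noise.

    Each blob's Gaussian sigma is chosen so the profile falls to
    ``support_fraction`` of its peak exactly at the drawn radius, i.e. the
    ground-truth support is the disk of that radius.  The image is clipped at
    zero and returned as float64 together with the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    K, M = spec.shape
    r_lo, r_hi = spec.radius_range

    radii = rng.uniform(r_lo, r_hi, spec.n_blobs)
    peaks = rng.uniform(*spec.peak_range, spec.n_blobs)
    n_dim = int(round(spec.dim_fraction * spec.n_blobs))
    if n_dim:
        dim_idx = rng.choice(spec.n_blobs, size=n_dim, replace=False)
        peaks[dim_idx] *= spec.dim_ratio

    margin = r_hi
    if spec.clustering == 0 or spec.n_blobs <= 1:
        centers = np.column_stack([
            rng.uniform(margin, K - margin, spec.n_blobs),
            rng.uniform(margin, M - margin, spec.n_blobs),
        ])
    else:
        n_clusters = max(1, spec.n_blobs // 8)
        anchors = np.column_stack([
            rng.uniform(margin, K - margin, n_clusters),
            rng.uniform(margin, M - margin, n_clusters),
        ])
        which = rng.integers(0, n_clusters, spec.n_blobs)
        spread = (1 - spec.clustering) * min(K, M) / 4 + spec.clustering * 1.5 * r_hi
        centers = anchors[which] + rng.normal(0.0, spread, (spec.n_blobs, 2))
        centers[:, 0] = np.clip(centers[:, 0], margin, K - margin)
        centers[:, 1] = np.clip(centers[:, 1], margin, M - margin)

    yy, xx = np.mgrid[0:K, 0:M]
    blobs = np.zeros((K, M))
    foreground = np.zeros((K, M), dtype=bool)
    # sigma so that exp(-r^2 / 2 sigma^2) = support_fraction at r = radius
    decay = np.sqrt(2.0 * np.log(1.0 / spec.support_fraction))
    for (cy, cx), radius, peak in zip(centers, radii, peaks):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        sigma = radius / decay
        blobs += peak * np.exp(-d2 / (2.0 * sigma**2))
        foreground |= d2 <= radius**2

    ramp = spec.gradient_amplitude * (yy + xx) / (K + M - 2) if K + M > 2 else 0.0
    image = spec.background_offset + ramp + blobs
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, (K, M))
    image = np.maximum(image, 0.0)

    truth = GroundTruth(
        background=~foreground, centers=centers, radii=radii, peaks=peaks
    )
    return image, truth


def background_f1(predicted_background: np.ndarray,
                  true_background: np.ndarray) -> float:
    """Pixelwise F1 score of the background class against ground truth."""
    pred = np.asarray(predicted_background, dtype=bool)
    true = np.asarray(true_background, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    tp = np.count_nonzero(pred & true)
    fp = np.count_nonzero(pred & ~true)
    fn = np.count_nonzero(~pred & true)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


# ---------------------------------------------------------------------------
# preset registry — frozen scene + filter parameterizations per regime

PRESETS: dict[str, NucleiSceneSpec] = {
    "large-background": NucleiSceneSpec(
        shape=(256, 256),
        n_blobs=25,
        radius_range=(6.0, 12.0),
        peak_range=(140.0, 250.0),
        dim_fraction=0.2,
        dim_ratio=0.25,
        background_offset=3.0,
        gradient_amplitude=1.5,
        noise_sd=1.0,
        clustering=0.0,
        seed=7,
    ),
    "large-foreground": NucleiSceneSpec(
        shape=(256, 256),
        n_blobs=110,
        radius_range=(7.0, 13.0),
        peak_range=(120.0, 250.0),
        dim_fraction=0.2,
        dim_ratio=0.3,
        background_offset=3.0,
        gradient_amplitude=1.0,
        noise_sd=1.0,
        clustering=0.7,
        seed=11,
    ),
    "fuzzy-foreground": NucleiSceneSpec(
        shape=(256, 256),
        n_blobs=60,
        radius_range=(7.0, 13.0),
        peak_range=(35.0, 55.0),
        dim_fraction=0.2,
        dim_ratio=0.5,
        background_offset=8.0,
        gradient_amplitude=2.0,
        noise_sd=2.0,
        clustering=0.3,
        seed=13,
    ),
}

# Filter settings documented per regime: theta plus either an explicit scale
# list or the gap-based selection rule.  Frozen alongside the scenes.
_PRESET_FILTERS: dict[str, dict] = {
    "large-background": {"theta": 0.5,
                         "select": {"max_gap": 80, "large_background": True,
                                    "min_scale": 5}},
    "large-foreground": {"theta": 0.5, "scales": (5, 10, 20, 40)},
    "fuzzy-foreground": {"theta": 0.95,
                         "select": {"max_gap": 80, "large_background": True,
                                    "min_scale": 5}},
}


def preset_filter_params(name: str, shape: tuple[int, int]
                         ) -> tuple[float, tuple[int, ...]]:
    """Resolve a preset's documented ``(theta, scales)`` for an image shape."""
    from .core import select_scales

    if name not in _PRESET_FILTERS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESET_FILTERS)}"
        )
    cfg = _PRESET_FILTERS[name]
    if "scales" in cfg:
        scales = cfg["scales"]
    else:
        sel = cfg["select"]
        scales = select_scales(
            sel["max_gap"], image_shape=shape,
            large_background=sel["large_background"],
            min_scale=sel["min_scale"],
        )
    return cfg["theta"], tuple(scales)


def write_fixture(spec: NucleiSceneSpec, outdir, stem: str = "fixture"
                  ) -> dict[str, Path]:
    """Write a scene as TIFF image + PNG mask + JSON sidecar of the spec."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image, truth = gen_nuclei_image(spec)
    paths = {
        "image": outdir / f"{stem}.tif",
        "mask": outdir / f"{stem}_background.png",
        "spec": outdir / f"{stem}.json",
    }
    tifffile.imwrite(paths["image"], image.astype(np.float32))
    iio.imwrite(paths["mask"],
                np.where(truth.background, 255, 0).astype(np.uint8))
    payload = dataclasses.asdict(spec)
    paths["spec"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
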