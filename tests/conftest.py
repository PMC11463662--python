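import numpy as np
import pytest


def naive_local_mean_1d(x, n):
    """Reference adaptive local mean: explicit per-sample window clipping."""
    x = np.asarray(x, dtype=float)
    K = x.size
    out = np.empty(K)
    for k in range(K):
        lo = max(k - n, 0)
        hi = min(k + n, K - 1) + 1
        out[k] = x[lo:hi].mean()
    return out


def naive_local_mean_2d(img, n):
    """Reference adaptive local mean: explicit double loop with clipping."""
    img = np.asarray(img, dtype=float)
    K, M = img.shape
    out = np.empty((K, M))
    for k in range(K):
        r0, r1 = max(k - n, 0), min(k + n, K - 1) + 1
        for m in range(M):
            c0, c1 = max(m - n, 0), min(m + n, M - 1) + 1
            out[k, m] = img[r0:r1, c0:c1].mean()
    return out


@pytest.fixture(scope="session")
def strip_image():
    """Bright slabs separated by a 40 px wide uniform low-level strip.

    Returns (image, strip column slice); strip half-width is 20 px.
    """
    img = np.full((160, 160), 100.0)
    strip = slice(60, 100)
    img[:, strip] = 5.0
    return img, strip
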