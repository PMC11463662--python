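"""Reading grayscale images, writing results, and run manifests.

TIFF is read/written with tifffile, PNG with imageio.  Filtered images keep
the input dtype; masks are written 8-bit with configurable polarity (default
foreground = 255, background = 0).  Every run writes a JSON manifest with
the exact parameters, input checksum, and output checksums so identical runs
are byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_gray", "read_stack", "write_outputs", "sha256_file"]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def read_gray(path, channel: int | None = None) -> np.ndarray:
    """Read a single-channel grayscale image.

    Multi-channel files (RGB PNG, multi-page TIFF) are ambiguous and require
    an explicit ``channel`` index; color axes are detected as the page axis
    of a TIFF stack or the trailing length-3/4 axis of an RGB(A) file.
    """
    path = Path(path)
    arr = _load(path)
    if arr.ndim == 2:
        pass
    elif arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} has {arr.shape} channels/pages; pass an explicit "
                "channel index to select one plane"
            )
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            arr = arr[..., channel]
        else:
            arr = arr[channel]
    else:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if np.any(arr < 0):
        raise ValueError(f"{path}: negative intensities are not supported")
    return arr


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF (or RGB image) as a (C, K, M) channel stack."""
    path = Path(path)
    arr = _load(path)
    if arr.ndim == 2:
        raise ValueError(
            f"{path} is single-channel; the co-localization input must be a "
            "multi-page TIFF or multi-channel image"
        )
    if arr.ndim != 3:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        arr = np.moveaxis(arr, -1, 0)
    if np.any(arr < 0):
        raise ValueError(f"{path}: negative intensities are not supported")
    return arr


def write_outputs(image: np.ndarray, mask: np.ndarray, outdir,
                  params: dict | None = None,
                  mask_polarity: str = "fg-white",
                  stem: str = "lmsf") -> dict[str, Path]:
    """Write the filtered image, the background mask, and a run manifest.

    ``mask_polarity`` controls only the written PNG: ``"fg-white"`` writes
    foreground as 255 (background black), ``"bg-white"`` the reverse.  The
    in-memory mask is untouched.  The manifest records parameters, versions,
    and sha256 checksums of everything written.
    """
    from . import __version__

    if mask_polarity not in ("fg-white", "bg-white"):
        raise ValueError(f"unknown mask polarity {mask_polarity!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    image_path = outdir / f"{stem}_filtered.tif"
    tifffile.imwrite(image_path, image)
    mask_path = outdir / f"{stem}_background.png"
    if mask_polarity == "fg-white":
        png = np.where(mask, 0, 255).astype(np.uint8)
    else:
        png = np.where(mask, 255, 0).astype(np.uint8)
    iio.imwrite(mask_path, png)

    manifest = {
        "tool": "lmsf",
        "version": __version__,
        "parameters": params or {},
        "dtype": str(image.dtype),
        "shape": list(image.shape),
        "mask_polarity": mask_polarity,
        "outputs": {
            image_path.name: sha256_file(image_path),
            mask_path.name: sha256_file(mask_path),
        },
    }
    manifest_path = outdir / f"{stem}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"image": image_path, "mask": mask_path, "manifest": manifest_path}
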