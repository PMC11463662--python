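"""Applications of the filter: co-localization class maps, denoising, display.

Multi-channel co-localization runs the cumulative filter independently on
each (pre-registered) channel and packs the per-channel foreground bits into
a single integer class map: channel 0 is the least significant bit, so a
pixel foreground in channels 0 and 2 of a 3-channel stack gets label
0b101 = 5 and a C-channel stack yields up to 2**C classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_THETA, cumulative_lmsf

__all__ = [
    "ChannelConfig",
    "colocalize",
    "masks_from_classmap",
    "class_area_table",
    "denoise",
    "gamma_display",
]

MAX_CHANNELS = 16


@dataclass(frozen=True)
class ChannelConfig:
    """Per-channel filter settings for co-localization."""

    name: str
    theta: float
    scales: tuple[int, ...]


def colocalize(channels: Sequence[np.ndarray],
               configs: Sequence[ChannelConfig]
               ) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-channel background masks and the combined class map.

    Channels must share one shape (registration is assumed to have been done
    upstream).  Returns ``(background_masks, classmap)`` where bit ``c`` of
    the class map is the foreground membership of channel ``c``.
    """
    if len(channels) == 0:
        raise ValueError("need at least one channel")
    if len(channels) > MAX_CHANNELS:
        raise ValueError(f"at most {MAX_CHANNELS} channels supported")
    if len(configs) != len(channels):
        raise ValueError(
            f"{len(channels)} channels but {len(configs)} channel configs"
        )
    shape = np.asarray(channels[0]).shape
    masks: list[np.ndarray] = []
    classmap = np.zeros(shape, dtype=np.uint32)
    for c, (chan, cfg) in enumerate(zip(channels, configs)):
        chan = np.asarray(chan)
        if chan.shape != shape:
            raise ValueError(
                f"channel {cfg.name!r} has shape {chan.shape}, "
                f"expected {shape}"
            )
        _, background = cumulative_lmsf(chan, cfg.scales, cfg.theta)
        masks.append(background)
        classmap |= (~background).astype(np.uint32) << c
    return masks, classmap


def masks_from_classmap(classmap: np.ndarray, n_channels: int
                        ) -> list[np.ndarray]:
    """Recover the per-channel *background* masks from a class map's bits."""
    cm = np.asarray(classmap)
    return [(cm >> c) & 1 == 0 for c in range(n_channels)]


def class_area_table(classmap: np.ndarray) -> pd.DataFrame:
    """Pixel count and area fraction per co-localization class.

    One row per label present in the map; counts sum to the pixel total and
    fractions to 1.
    """
    cm = np.asarray(classmap)
    labels, counts = np.unique(cm, return_counts=True)
    return pd.DataFrame({
        "label": labels.astype(int),
        "pixel_count": counts.astype(int),
        "fraction": counts / cm.size,
    })


def denoise(image, scales, theta: float = DEFAULT_THETA) -> np.ndarray:
    """Zero the identified background as a pre-segmentation denoising step.

    Alias for the image output of the cumulative filter: background pixels
    are set to 0, foreground pixels keep their exact input value, so the
    result feeds directly into downstream instance segmenters.
    """
    filtered, _ = cumulative_lmsf(image, scales, theta)
    return filtered


def gamma_display(image, gamma: float = 0.5) -> np.ndarray:
    """Display-only power-law transform to reveal dim structure.

    Normalizes by the image maximum (an all-zero image maps to itself) and
    raises to ``gamma``; never fed back into filtering.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    img = np.asarray(image, dtype=np.float64)
    peak = img.max(initial=0.0)
    if peak == 0:
        return np.zeros_like(img)
    return (img / peak) ** gamma
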