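"""Two-channel colocalization and per-synapse signal levels.

Quantifies supported-lipid-bilayer / vesicle interface images the way
per-contact violin plots are built: segment cell footprints, then compute
one Pearson correlation (and/or one background-subtracted, reference-
normalized mean level) per connected contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

from .errors import NormalizationError, ValidationError

__all__ = [
    "SynapseImage",
    "CellQuantRow",
    "footprint_mask",
    "background_region",
    "pearson_colocalization",
    "normalized_level",
    "quantify_cells",
]


@dataclass
class SynapseImage:
    """Named 2-D intensity channels sharing one shape and pixel size (um)."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # um per pixel
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("image needs at least one channel")
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be positive (um/pixel)")
        shape = None
        for name, arr in list(self.channels.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"channel {name!r} is not 2-D")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValidationError("all channels must share one shape")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"channel {name!r} has non-finite or negative pixels")
            self.channels[name] = arr
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValidationError("mask shape must match the channels")
        self.shape = shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ValidationError(f"unknown channel {name!r}")
        return self.channels[name]


@dataclass
class CellQuantRow:
    """One contact's quantification: Pearson r's, normalized levels, area."""

    cell_id: int
    area_um2: float
    pearson: dict[str, float] = field(default_factory=dict)
    level: dict[str, float] = field(default_factory=dict)


def footprint_mask(
    image: SynapseImage,
    channel: str,
    method: str = "otsu",
    min_area_um2: float = 1.0,
    fixed_threshold: float | None = None,
) -> list[np.ndarray]:
    """Segment cell footprints on one channel; one boolean mask per cell.

    Connected components above the threshold (Otsu or fixed) and at least
    ``min_area_um2`` in area are kept. An empty result triggers a
    no-cells warning rather than an error.
    """
    arr = image.channel(channel)
    if method == "otsu":
        if np.ptp(arr) == 0:
            warnings.warn("blank channel: no cells found", stacklevel=2)
            return []
        thr = filters.threshold_otsu(arr)
    elif method == "fixed_threshold":
        if fixed_threshold is None:
            raise ValidationError("fixed_threshold method requires a threshold value")
        thr = fixed_threshold
    else:
        raise ValidationError(f"unknown method {method!r}")
    binary = arr > thr
    labeled = measure.label(binary)
    min_pixels = min_area_um2 / image.pixel_size**2
    masks = []
    for region in measure.regionprops(labeled):
        if region.area >= min_pixels:
            masks.append(labeled == region.label)
    if not masks:
        warnings.warn("no cells above threshold/min-area", stacklevel=2)
    return masks


def background_region(
    image: SynapseImage, cell_masks: list[np.ndarray], dilation_um: float = 2.0
) -> np.ndarray:
    """Background pixels: everything outside every cell mask dilated by a margin.

    The dilation excludes the halo around each contact from the background
    estimate; by construction the result is disjoint from every cell mask.
    """
    union = np.zeros(image.shape, dtype=bool)
    for m in cell_masks:
        union |= m
    radius = max(1, int(round(dilation_um / image.pixel_size)))
    dilated = morphology.dilation(union, morphology.disk(radius))
    bg = ~dilated
    if not bg.any():
        raise ValidationError("no background pixels left after dilation")
    return bg


def pearson_colocalization(
    image: SynapseImage, channel_a: str, channel_b: str, mask: np.ndarray
) -> float:
    """Sample Pearson correlation of two channels over the mask pixels.

    Raises on fewer than 10 mask pixels or a constant channel in the mask
    (an undefined correlation is reported as missing, never coerced to 0).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 10:
        raise ValidationError("mask has fewer than 10 pixels")
    a = image.channel(channel_a)[mask]
    b = image.channel(channel_b)[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("constant channel within mask: correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r)


def normalized_level(
    image: SynapseImage,
    channel: str,
    mask: np.ndarray,
    background_mask: np.ndarray,
    reference_scale: float,
) -> float:
    """Background-subtracted mean level in a contact, normalized per batch.

    (mean in mask - mean background) / reference_scale, where the
    reference scale is the batch median of the same raw quantity over a
    declared reference condition (see :func:`quantify_cells`).
    """
    mask = np.asarray(mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if np.any(mask & background_mask):
        raise ValidationError("background region overlaps the cell mask")
    if reference_scale <= 0:
        raise NormalizationError("reference scale must be positive")
    arr = image.channel(channel)
    return float((arr[mask].mean() - arr[background_mask].mean()) / reference_scale)


def raw_level(image: SynapseImage, channel: str, mask, background_mask) -> float:
    """Un-normalized background-subtracted mean; feeds the reference median."""
    return normalized_level(image, channel, mask, background_mask, 1.0)


def quantify_cells(
    image: SynapseImage,
    pearson_pairs: list[tuple[str, str]] | None = None,
    level_channels: list[str] | None = None,
    mask_channel: str | None = None,
    cell_masks: list[np.ndarray] | None = None,
    reference_scales: dict[str, float] | None = None,
    min_area_um2: float = 1.0,
    dilation_um: float = 2.0,
) -> pd.DataFrame:
    """Per-cell quantification table (one row per contact).

    Cells come either from ``cell_masks`` or by segmenting ``mask_channel``.
    Pearson r is computed for each requested channel pair; normalized
    levels for each requested channel, divided by the channel's entry in
    ``reference_scales`` (default 1.0, i.e. raw background-subtracted
    levels, from which a caller derives the batch reference median).
    Undefined correlations are left as NaN.
    """
    if cell_masks is None:
        if mask_channel is None:
            raise ValidationError("either cell_masks or mask_channel is required")
        cell_masks = footprint_mask(image, mask_channel, min_area_um2=min_area_um2)
    rows = []
    if not cell_masks:
        return pd.DataFrame(rows)
    bg = background_region(image, cell_masks, dilation_um=dilation_um)
    for cid, mask in enumerate(cell_masks, start=1):
        row: dict = {
            "cell_id": cid,
            "area_um2": float(mask.sum()) * image.pixel_size**2,
        }
        for a, b in pearson_pairs or []:
            try:
                row[f"pearson_{a}_{b}"] = pearson_colocalization(image, a, b, mask)
            except ValidationError:
                row[f"pearson_{a}_{b}"] = np.nan
        for ch in level_channels or []:
            scale = (reference_scales or {}).get(ch, 1.0)
            row[f"level_{ch}"] = normalized_level(image, ch, mask, bg, scale)
        rows.append(row)
    return pd.DataFrame(rows)
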