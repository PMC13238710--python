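"""Marker abundance from fluorescence channels.

Mean fluorescence intensity (MFI) is the arithmetic mean of channel
intensities over nerve-fiber pixels inside a region of interest. No
background subtraction or flat-field correction is applied: the inputs are
treated as the vendor-processed projections they are, and normalization to a
pan-neuronal reference marker (PGP9.5) is the control for staining and
imaging variability — a ratio is invariant to any global intensity scale.

An empty nerve-within-ROI intersection yields a *missing* MFI, never zero:
absence of fibers is not absence of signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .masks import RasterMask, mask_area

__all__ = ["ChannelImage", "MfiRecord", "mfi", "normalized_mfi", "area_ratio"]


@dataclass(frozen=True)
class ChannelImage:
    """Single fluorescence channel with marker identity and pixel size."""

    grid: np.ndarray  # 2D nonnegative intensities (12/16-bit range)
    marker: str
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError(f"channel grid must be 2D, got shape {grid.shape}")
        if np.nanmin(grid) < 0:
            raise ValueError("channel intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class MfiRecord:
    marker: str
    roi_name: str
    mfi: float  # NaN = missing
    pixel_count: int
    normalized_to: str | None = None
    normalized_mfi: float | None = None

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.mfi)


def _check_shapes(channel: ChannelImage, *masks: RasterMask) -> None:
    for m in masks:
        if m.shape != channel.grid.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match channel shape {channel.grid.shape}"
            )


def mfi(
    channel: ChannelImage,
    nerve: RasterMask,
    roi: RasterMask,
    roi_name: str = "roi",
) -> MfiRecord:
    """Mean channel intensity over nerve-fiber pixels inside ``roi``."""
    _check_shapes(channel, nerve, roi)
    sel = nerve.grid & roi.grid
    n = int(sel.sum())
    if n == 0:
        return MfiRecord(marker=channel.marker, roi_name=roi_name, mfi=float("nan"), pixel_count=0)
    value = float(np.mean(channel.grid[sel]))
    return MfiRecord(marker=channel.marker, roi_name=roi_name, mfi=value, pixel_count=n)


def normalized_mfi(target: MfiRecord, reference: MfiRecord) -> MfiRecord:
    """Ratio of a target marker's MFI to a reference marker's MFI.

    Both records must come from the same ROI. A missing or zero reference
    propagates a missing ratio.
    """
    if target.roi_name != reference.roi_name:
        raise ValueError(
            f"cannot normalize across ROIs: {target.roi_name!r} vs {reference.roi_name!r}"
        )
    if target.missing or reference.missing or reference.mfi == 0:
        ratio = float("nan")
    else:
        ratio = target.mfi / reference.mfi
    return dataclasses.replace(target, normalized_to=reference.marker, normalized_mfi=ratio)


def area_ratio(
    marker_mask: RasterMask, total_mask: RasterMask, roi: RasterMask
) -> float:
    """area(marker within roi) / area(total within roi), in [0, 1].

    Missing (NaN) when the total marker covers no ROI pixel. A ratio above 1
    indicates the marker-positive mask escapes the total mask (segmentation
    inconsistency) and is returned as-is with a warning.
    """
    denom = mask_area(total_mask, roi)
    if denom == 0:
        return float("nan")
    ratio = mask_area(marker_mask, roi) / denom
    if ratio > 1:
        warnings.warn(
            f"area ratio {ratio:.3f} > 1: marker mask extends outside the total mask",
            stacklevel=2,
        )
    return ratio
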