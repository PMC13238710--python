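"""Dermal vessel quantification and vessel-nerve interaction area.

A nerve fiber proximity region is the set of pixels within a fixed radius
(default 5 um) of any nerve fiber pixel, fibers included. The interaction
area is the dermal blood-vessel area falling inside that region. Analysis is
restricted to the dermis; epidermal vessel pixels (segmentation noise) are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masks import RasterMask, _check_compatible, expand_mask, mask_area

__all__ = ["VesselMetrics", "nerve_proximity_region", "interaction_area"]


@dataclass(frozen=True)
class VesselMetrics:
    vessel_area_um2: float
    interaction_area_um2: float
    proximity_radius_um: float


def nerve_proximity_region(nerve: RasterMask, radius_um: float = 5.0) -> RasterMask:
    """Pixels within ``radius_um`` of the nerve fibers (closed ball)."""
    if not radius_um > 0:
        raise ValueError(f"proximity radius must be > 0, got {radius_um}")
    return expand_mask(nerve, radius_um)


def interaction_area(
    vessels: RasterMask,
    nerve: RasterMask,
    dermis: RasterMask,
    radius_um: float = 5.0,
) -> VesselMetrics:
    """Dermal vessel area and the part of it within the nerve proximity region."""
    _check_compatible(vessels, nerve)
    _check_compatible(vessels, dermis)
    if not dermis.grid.any():
        raise ValueError("dermis mask is empty; vessel metrics are defined in the dermis")
    dermal_vessels = vessels.intersect(dermis)
    proximity = nerve_proximity_region(nerve, radius_um)
    return VesselMetrics(
        vessel_area_um2=dermal_vessels.area_um2,
        interaction_area_um2=mask_area(dermal_vessels, proximity),
        proximity_radius_um=float(radius_um),
    )
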