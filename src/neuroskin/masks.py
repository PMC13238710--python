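"""Mask morphometry in physical units.

Binary segmentation masks (epidermis, dermis, nerve fibers, blood vessels)
live on a common pixel lattice; every reported quantity carries micrometer
units derived from the acquisition pixel size (isotropic, e.g. 0.61 um/px).

Distance convention: Euclidean distance between pixel centers; pixel (r, c)
has center (r + 0.5, c + 0.5) in pixel units. A pixel belongs to a region
expanded by ``d`` micrometers when its center lies within the *closed* ball
of radius ``d`` around any foreground pixel center. Expansion is clipped at
the image border without compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

__all__ = [
    "RasterMask",
    "RoiSet",
    "BasementMembrane",
    "expand_mask",
    "derive_subepidermis",
    "resolve_overlap",
    "basement_membrane",
    "mask_area",
    "derive_rois",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RasterMask:
    """A binary raster with isotropic physical pixel size.

    Parameters
    ----------
    grid
        2D boolean array (rows x cols). Any array-like is coerced to bool.
    pixel_size_um
        Micrometers per pixel edge; must be positive.
    """

    grid: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValueError(f"mask grid must be 2D and at least 1x1, got shape {grid.shape}")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "pixel_size_um", float(self.pixel_size_um))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    @property
    def area_um2(self) -> float:
        return self.n_foreground * self.pixel_size_um**2

    def intersect(self, other: "RasterMask") -> "RasterMask":
        _check_compatible(self, other)
        return RasterMask(self.grid & other.grid, self.pixel_size_um)

    def union(self, other: "RasterMask") -> "RasterMask":
        _check_compatible(self, other)
        return RasterMask(self.grid | other.grid, self.pixel_size_um)


def _check_compatible(a: RasterMask, b: RasterMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ in shape: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_size_um, b.pixel_size_um, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"masks differ in pixel size: {a.pixel_size_um} vs {b.pixel_size_um} um"
        )


def expand_mask(mask: RasterMask, distance_um: float) -> RasterMask:
    """Dilate a mask by a physical distance (closed Euclidean ball).

    The result contains exactly the pixels whose center-to-nearest-foreground
    center distance is <= ``distance_um``; foreground pixels are kept
    (distance 0). Empty masks stay empty.
    """
    if distance_um < 0:
        raise ValueError(f"expansion distance must be >= 0, got {distance_um}")
    if distance_um == 0 or not mask.grid.any():
        return RasterMask(mask.grid.copy(), mask.pixel_size_um)
    # exact Euclidean distance (pixel units) to nearest foreground center
    dist_px = ndi.distance_transform_edt(~mask.grid)
    radius_px = distance_um / mask.pixel_size_um
    return RasterMask(dist_px <= radius_px, mask.pixel_size_um)


def resolve_overlap(epidermis: RasterMask, dermis: RasterMask) -> tuple[RasterMask, RasterMask]:
    """Assign epidermis/dermis overlap pixels to the epidermis.

    Segmentation tools may emit overlapping class masks; downstream geometry
    requires disjoint classes. Overlap pixels are removed from the dermis.
    """
    _check_compatible(epidermis, dermis)
    return epidermis, RasterMask(dermis.grid & ~epidermis.grid, dermis.pixel_size_um)


def derive_subepidermis(
    epidermis: RasterMask, dermis: RasterMask, distance_um: float = 50.0
) -> RasterMask:
    """Dermal band within ``distance_um`` (default 50 um) of the epidermis.

    Computed by expanding the epidermis and intersecting with the dermis.
    The inputs must be disjoint; use :func:`resolve_overlap` first if the
    segmentation emits overlapping classes.
    """
    _check_compatible(epidermis, dermis)
    n_overlap = int((epidermis.grid & dermis.grid).sum())
    if n_overlap:
        raise ValueError(
            f"epidermis and dermis masks overlap in {n_overlap} pixels; "
            "resolve the overlap explicitly (see resolve_overlap) before deriving the sub-epidermis"
        )
    expanded = expand_mask(epidermis, distance_um)
    return expanded.intersect(dermis)


@dataclass(frozen=True)
class BasementMembrane:
    """The epidermis-dermis interface.

    ``band`` is the one-pixel crossing band: dermis pixels 8-adjacent to the
    epidermis. Using 8-adjacency guarantees that any 8-connected path from
    epidermis into dermis touches the band (no diagonal tunneling).
    ``polylines`` are ordered pixel-center coordinates, one array per
    connected interface segment, traced on the skeletonized band so that
    staircase steps contribute sqrt(2) rather than 2 pixel lengths.
    """

    polylines: list  # list of (k, 2) float arrays of (row, col) pixel centers
    band: RasterMask
    length_mm: float


def _trace_chain(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Order curve pixels into a polyline by greedy nearest-neighbor walking.

    Returns the ordered coordinates and the arc length in pixel units.
    Deterministic: coordinates are pre-sorted lexicographically and ties in
    the walk resolve to the lexicographically smallest candidate.
    """
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    k = len(coords)
    if k == 1:
        return coords.astype(float), 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = (diff.astype(np.int64) ** 2).sum(axis=2).astype(float)
    adj = (d2 <= 2) & (d2 > 0)
    # start at an endpoint (fewest 8-neighbors on the curve)
    start = int(np.argmin(adj.sum(axis=1)))
    visited = np.zeros(k, dtype=bool)
    path = np.empty(k, dtype=int)
    current = start
    length = 0.0
    for i in range(k):
        path[i] = current
        visited[current] = True
        if i == k - 1:
            break
        row = d2[current].copy()
        row[visited] = np.inf
        nxt = int(np.argmin(row))
        length += float(np.sqrt(row[nxt]))
        current = nxt
    return coords[path].astype(float), length


def basement_membrane(epidermis: RasterMask, dermis: RasterMask) -> BasementMembrane:
    """Extract the epidermis-dermis interface and its physical length.

    The interface is the counting line for nerve fiber density; the free
    epidermal surface never contributes. Length uses an arc-length-plus-one
    pixel convention per segment, so a straight full-width interface measures
    exactly ``width * pixel_size``. Raises ``ValueError`` when the two
    classes are nowhere adjacent.
    """
    _check_compatible(epidermis, dermis)
    band_grid = ndi.binary_dilation(epidermis.grid, structure=_STRUCT8) & dermis.grid
    if not band_grid.any():
        raise ValueError("no basement membrane found: epidermis and dermis are nowhere adjacent")
    skel = skeletonize(band_grid)
    if not skel.any():  # degenerate tiny band
        skel = band_grid
    labels, n = ndi.label(skel, structure=_STRUCT8)
    polylines = []
    total_px = 0.0
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i)
        chain, arc = _trace_chain(coords)
        polylines.append(chain + 0.5)
        total_px += arc + 1.0  # half-pixel end caps cover the full extent
    length_mm = total_px * epidermis.pixel_size_um / 1000.0
    return BasementMembrane(
        polylines=polylines,
        band=RasterMask(band_grid, epidermis.pixel_size_um),
        length_mm=length_mm,
    )


def mask_area(mask: RasterMask, roi: RasterMask | None = None) -> float:
    """Foreground area in um^2, optionally restricted to ``roi``."""
    if roi is None:
        return mask.area_um2
    return mask.intersect(roi).area_um2


@dataclass(frozen=True)
class RoiSet:
    """Regions of interest for one annotated section.

    ``subepidermis`` is the dermal band within the configured expansion
    distance of the epidermis; ``membrane`` carries the interface polyline,
    crossing band and physical length.
    """

    epidermis: RasterMask
    dermis: RasterMask
    subepidermis: RasterMask
    membrane: BasementMembrane
    expansion_um: float = field(default=50.0)


def derive_rois(
    epidermis: RasterMask, dermis: RasterMask, expansion_um: float = 50.0
) -> RoiSet:
    """Derive the full ROI set from epidermis + dermis masks."""
    sub = derive_subepidermis(epidermis, dermis, expansion_um)
    membrane = basement_membrane(epidermis, dermis)
    return RoiSet(
        epidermis=epidermis,
        dermis=dermis,
        subepidermis=sub,
        membrane=membrane,
        expansion_um=float(expansion_um),
    )
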