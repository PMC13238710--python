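"""Synthetic annotated skin sections and cohorts with known ground truth.

The generator emulates the geometry and statistics a skin-section
quantification pipeline assumes: an undulating epidermal band over dermis,
curvilinear nerve fibers that cross the basement membrane at a programmable
rate (plus purely dermal fibers), elliptical dermal vessels placed at
programmable center-to-fiber distances, per-channel fiber intensities with
additive truncated-Gaussian noise, and cohort-level group effects (reduced
fiber density and elevated TrkA intensity in patients, elevated
vessel-nerve interaction in the painless subgroup only).

Testability is the design driver: every planted quantity is recoverable by
the corresponding pipeline operation. Crossing fibers run strictly
vertically through the undulation zone, so each planted fiber touches the
interface in exactly one connected locus, making planted count == countable
count; vessels are centered on pixels whose exact Euclidean distance to the
nearest fiber matches the requested target within half a pixel.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .fluorescence import ChannelImage
from .masks import RasterMask

__all__ = [
    "ChannelModel",
    "VesselPlacement",
    "SectionSpec",
    "GroundTruth",
    "AnnotatedSection",
    "generate_section",
    "threshold_segment",
    "CohortSpec",
    "SubjectRecord",
    "iter_cohort",
    "generate_cohort",
    "draw_qst_from_norms",
    "generate_ct_table",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ChannelModel:
    """Intensity model for one fluorescence channel.

    ``on`` selects which fibers carry the marker: "all" nerve fibers or the
    "cgrp" (peptidergic) subset.
    """

    fiber_mean: float
    background_mean: float = 200.0
    noise_sd: float = 50.0
    on: str = "all"  # "all" | "cgrp"


@dataclass(frozen=True)
class VesselPlacement:
    """One dermal vessel.

    ``distance_um`` is the target center-to-nearest-fiber distance; ``None``
    places the vessel clear of the 5 um proximity analysis (background
    vessel). ``axis_ratio`` elongates the ellipse (1 = circle); planted-
    distance vessels are always circles so the nearest-point distance is
    exactly ``distance - radius``.
    """

    radius_um: float = 5.0
    distance_um: float | None = None
    axis_ratio: float = 1.0


def _default_channels() -> dict:
    return {
        "PGP9.5": ChannelModel(2000.0),
        "CGRP": ChannelModel(1800.0, on="cgrp"),
        "TrkA": ChannelModel(1500.0),
        "GAP43": ChannelModel(1200.0),
    }


def _default_vessels() -> tuple:
    near = tuple(VesselPlacement(radius_um=5.0, distance_um=8.0) for _ in range(2))
    far = tuple(VesselPlacement(radius_um=5.0, distance_um=None, axis_ratio=1.3) for _ in range(6))
    return near + far


@dataclass
class SectionSpec:
    """Parameters of one synthetic annotated section."""

    shape: tuple = (1024, 1024)
    pixel_size_um: float = 0.61
    epidermis_depth_px: int = 120
    undulation_amplitude_px: float = 15.0
    undulation_wavelength_px: float = 300.0
    n_crossing_fibers: int = 8
    n_dermal_fibers: int = 4
    fiber_width_px: int = 3
    fiber_spacing_px: int = 16
    fiber_step_sd: float = 0.6
    epidermal_penetration_px: int = 40
    dermal_depth_px: int = 250
    dermal_fiber_length_px: int = 150
    cgrp_fraction: float = 0.5
    vessels: tuple = field(default_factory=_default_vessels)
    channels: dict = field(default_factory=_default_channels)
    bit_depth: int = 16
    seed: int | None = 0


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities, consistent with the emitted masks by construction."""

    crossing_count: int
    membrane_length_mm: float
    fiber_mean_intensity: dict
    nerve_area_um2: float
    cgrp_area_um2: float
    vessel_area_um2: float
    interaction_area_um2: float
    proximity_radius_um: float
    vessel_distances_um: tuple
    n_dermal_fibers: int


@dataclass(frozen=True)
class AnnotatedSection:
    """Multi-channel image plus structure masks on one pixel grid."""

    channels: dict  # marker -> ChannelImage
    masks: dict  # {"epidermis","dermis","nerve","vessels","cgrp"} -> RasterMask
    pixel_size_um: float


def _boundary_rows(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.shape
    amp, lam = spec.undulation_amplitude_px, spec.undulation_wavelength_px
    if amp > 0 and amp * 2 * np.pi / lam > 0.9:
        raise ValueError(
            "infeasible undulation: boundary slope exceeds 0.9 px/px "
            f"(amplitude {amp}, wavelength {lam})"
        )
    if spec.epidermis_depth_px - amp < 2:
        raise ValueError("epidermis depth minus undulation amplitude must leave >= 2 rows")
    phase = rng.uniform(0, 2 * np.pi)
    cols = np.arange(W)
    b_float = spec.epidermis_depth_px + amp * np.sin(2 * np.pi * cols / lam + phase)
    b = np.rint(b_float).astype(int)
    if b.min() < 2 or b.max() > H - 4:
        raise ValueError("epidermal boundary leaves the image frame")
    return b


def _crossing_columns(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_crossing_fibers
    if n == 0:
        return np.empty(0, dtype=int)
    W = spec.shape[1]
    s = max(spec.fiber_spacing_px, 2 * spec.fiber_width_px + 3)
    margin = s
    usable = W - 2 * margin - (n - 1) * s
    if usable < 0:
        raise ValueError(
            f"infeasible: {n} crossing fibers at spacing {s} px do not fit "
            f"an interface of width {W} px"
        )
    offsets = np.sort(rng.integers(0, usable + 1, size=n))
    return margin + offsets + np.arange(n) * s


def _walk_fiber(
    spec: SectionSpec,
    rng: np.random.Generator,
    c0: int,
    b: np.ndarray,
    crossing: bool,
) -> np.ndarray:
    """Path pixels (row, col) of a single fiber centerline."""
    H, W = spec.shape
    bmin, bmax = int(b.min()), int(b.max())
    w = spec.fiber_width_px
    s = max(spec.fiber_spacing_px, 2 * w + 3)
    max_dev = max(0, (s - 2 * w - 2) // 2)
    if crossing:
        r_bottom = min(bmax + spec.dermal_depth_px, H - 3)
        r_top = max(bmin - spec.epidermal_penetration_px, 1)
        col = int(c0)
        pts = []
        for r in range(r_bottom, r_top - 1, -1):
            if r > bmax + 2 or r < bmin - 2:
                step = int(np.clip(np.rint(rng.normal(0.0, spec.fiber_step_sd)), -1, 1))
                col = int(np.clip(col + step, c0 - max_dev, c0 + max_dev))
                col = int(np.clip(col, 1, W - 2))
            # inside the undulation zone the fiber runs vertically: exactly
            # one interface contact per planted crossing fiber
            pts.append((r, col))
        return np.array(pts, dtype=int)
    # dermal-only fiber: horizontal-ish walk well below the interface band
    r_lo = bmax + w + 4
    r_hi = H - 6
    if r_lo >= r_hi:
        raise ValueError("infeasible: no dermal room for a non-crossing fiber")
    row = int(rng.integers(r_lo, r_hi + 1))
    cstart = int(rng.integers(1, max(2, W - 1 - spec.dermal_fiber_length_px)))
    pts = []
    for c in range(cstart, min(cstart + spec.dermal_fiber_length_px, W - 1)):
        step = int(np.clip(np.rint(rng.normal(0.0, spec.fiber_step_sd)), -1, 1))
        row = int(np.clip(row + step, r_lo, r_hi))
        pts.append((row, c))
    return np.array(pts, dtype=int)


def _rasterize_paths(paths, shape, width_px: int) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    for pts in paths:
        grid[pts[:, 0], pts[:, 1]] = True
    radius = width_px // 2
    if radius > 0:
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        disk = (yy**2 + xx**2) <= radius**2
        grid = ndi.binary_dilation(grid, structure=disk)
    return grid


def _place_vessels(
    spec: SectionSpec,
    rng: np.random.Generator,
    dermis: np.ndarray,
    nerve: np.ndarray,
    epi: np.ndarray,
):
    H, W = spec.shape
    ps = spec.pixel_size_um
    if nerve.any():
        dist_px = ndi.distance_transform_edt(~nerve)
    else:
        dist_px = np.full(spec.shape, np.inf)
    epi_dist = ndi.distance_transform_edt(~epi)
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    vessel_grid = np.zeros(spec.shape, dtype=bool)
    planted = []
    for v in spec.vessels:
        r_px = v.radius_um / ps
        r_major = r_px * max(v.axis_ratio, 1.0)
        frame_ok = (
            (rows > r_major + 2) & (rows < H - r_major - 3)
            & (cols > r_major + 2) & (cols < W - r_major - 3)
        )
        eligible = dermis & (epi_dist > r_major + 2) & frame_ok
        if v.distance_um is None:
            # background vessel: keep its rim clear of the proximity analysis
            clearance = r_major + (5.0 / ps) + 3
            cand = eligible & (dist_px >= clearance)
        else:
            d_px = v.distance_um / ps
            if d_px < r_px + 1:
                raise ValueError(
                    f"infeasible vessel: planted distance {v.distance_um} um places the "
                    f"vessel (radius {v.radius_um} um) onto the fiber"
                )
            cand = eligible & (np.abs(dist_px - d_px) <= 0.5)
            if not cand.any():
                cand = eligible & (np.abs(dist_px - d_px) <= 1.0)
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            raise ValueError("infeasible vessel placement: no eligible center pixel")
        placed = False
        for trial in rng.permutation(idx)[:100]:
            r, c = divmod(int(trial), W)
            if v.distance_um is None:
                rr, cc = draw_ellipse(r, c, r_px * v.axis_ratio, r_px / max(v.axis_ratio, 1e-9))
            else:
                rr, cc = draw_ellipse(r, c, r_px, r_px)
            rr = np.clip(rr, 0, H - 1)
            cc = np.clip(cc, 0, W - 1)
            if vessel_grid[rr, cc].any():
                continue
            vessel_grid[rr, cc] = True
            planted.append(float(dist_px[r, c] * ps) if v.distance_um is not None else np.inf)
            placed = True
            break
        if not placed:
            raise ValueError("infeasible vessel placement: could not avoid existing vessels")
    return vessel_grid, dist_px, tuple(planted)


def generate_section(spec: SectionSpec) -> tuple[AnnotatedSection, GroundTruth]:
    """Generate one annotated section plus its ground truth."""
    if spec.n_crossing_fibers < 0 or spec.n_dermal_fibers < 0:
        raise ValueError("fiber counts must be >= 0")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    ps = spec.pixel_size_um

    b = _boundary_rows(spec, rng)
    rows = np.arange(H)[:, None]
    epi = rows < b[None, :]
    dermis = ~epi
    true_length_mm = float((np.hypot(1.0, np.diff(b)).sum() + 1.0) * ps / 1000.0)

    cross_cols = _crossing_columns(spec, rng)
    fiber_paths = [_walk_fiber(spec, rng, c, b, crossing=True) for c in cross_cols]
    fiber_paths += [
        _walk_fiber(spec, rng, 0, b, crossing=False) for _ in range(spec.n_dermal_fibers)
    ]
    fiber_masks = [
        _rasterize_paths([p], spec.shape, spec.fiber_width_px) for p in fiber_paths
    ]
    nerve = np.zeros(spec.shape, dtype=bool)
    for m in fiber_masks:
        nerve |= m
    n_fibers = len(fiber_paths)
    is_cgrp = rng.random(n_fibers) < spec.cgrp_fraction if n_fibers else np.empty(0, bool)
    cgrp = np.zeros(spec.shape, dtype=bool)
    for m, flag in zip(fiber_masks, is_cgrp):
        if flag:
            cgrp |= m

    vessel_grid, nerve_dist_px, planted_d = _place_vessels(spec, rng, dermis, nerve, epi)
    proximity = nerve_dist_px <= 5.0 / ps
    interaction_px = int((vessel_grid & dermis & proximity).sum())

    max_val = 2**spec.bit_depth - 1
    channels = {}
    for marker, model in spec.channels.items():
        img = rng.normal(model.background_mean, model.noise_sd, spec.shape)
        sel = nerve if model.on == "all" else cgrp
        n_sel = int(sel.sum())
        if n_sel:
            img[sel] = rng.normal(model.fiber_mean, model.noise_sd, n_sel)
        np.clip(img, 0, max_val, out=img)
        channels[marker] = ChannelImage(
            grid=np.rint(img).astype(np.uint16), marker=marker,
            pixel_size_um=ps, bit_depth=spec.bit_depth,
        )

    masks = {
        "epidermis": RasterMask(epi, ps),
        "dermis": RasterMask(dermis, ps),
        "nerve": RasterMask(nerve, ps),
        "vessels": RasterMask(vessel_grid, ps),
        "cgrp": RasterMask(cgrp, ps),
    }
    truth = GroundTruth(
        crossing_count=spec.n_crossing_fibers,
        membrane_length_mm=true_length_mm,
        fiber_mean_intensity={m: mod.fiber_mean for m, mod in spec.channels.items()},
        nerve_area_um2=float(nerve.sum()) * ps**2,
        cgrp_area_um2=float(cgrp.sum()) * ps**2,
        vessel_area_um2=float((vessel_grid & dermis).sum()) * ps**2,
        interaction_area_um2=interaction_px * ps**2,
        proximity_radius_um=5.0,
        vessel_distances_um=planted_d,
        n_dermal_fibers=spec.n_dermal_fibers,
    )
    return AnnotatedSection(channels=channels, masks=masks, pixel_size_um=ps), truth


def threshold_segment(channel: ChannelImage, threshold: float) -> RasterMask:
    """Global-threshold segmentation stand-in for end-to-end demos."""
    if not 0 <= threshold <= 2**channel.bit_depth - 1:
        raise ValueError(
            f"threshold {threshold} outside the {channel.bit_depth}-bit range"
        )
    return RasterMask(np.asarray(channel.grid) >= threshold, channel.pixel_size_um)


# --------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Three-group cohort with planted effects.

    Group effects mirror the qualitative clinical pattern: patients (both
    pain phenotypes) get the fiber-density and TrkA-intensity multipliers,
    the NGF fold and the vessel-area multiplier; only the painless subgroup
    gets the vessel-nerve interaction multiplier.
    """

    n_control: int = 20
    n_painless: int = 20
    n_painful: int = 20
    images_per_subject: int = 2
    base_crossings: int = 16
    ienfd_multiplier: float = 0.5
    trka_multiplier: float = 5.0
    ngf_fold: float = 0.75
    trka_fold: float = 1.0  # gene expression: no substantial group difference
    vessel_area_multiplier: float = 1.4
    interaction_multiplier: float = 3.0
    base_near_vessels: int = 2
    subject_cv: float = 0.1
    section: SectionSpec = field(default_factory=SectionSpec)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ienfd_multiplier", "trka_multiplier", "ngf_fold",
                     "vessel_area_multiplier", "interaction_multiplier"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.n_control, self.n_painless, self.n_painful) < 3:
            raise ValueError("need n >= 3 per group (normality-test minimum downstream)")

    @property
    def groups(self) -> list:
        return (
            ["control"] * self.n_control
            + ["painless"] * self.n_painless
            + ["painful"] * self.n_painful
        )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    sections: list  # AnnotatedSection per image
    truths: list  # GroundTruth per image
    planted: dict  # subject-level multipliers actually applied


def _draw_subject_effects(spec: CohortSpec, group: str, rng: np.random.Generator) -> dict:
    """Subject-level multipliers: group effect x lognormal inter-subject noise."""
    patient = group != "control"
    cv = spec.subject_cv
    m_ien = (spec.ienfd_multiplier if patient else 1.0) * rng.lognormal(0.0, cv)
    m_trka = (spec.trka_multiplier if patient else 1.0) * rng.lognormal(0.0, cv)
    m_varea = (spec.vessel_area_multiplier if patient else 1.0) * rng.lognormal(0.0, cv / 2)
    m_inter = spec.interaction_multiplier if group == "painless" else 1.0
    return {
        "ienfd_multiplier": m_ien,
        "trka_multiplier": m_trka,
        "vessel_area_multiplier": m_varea,
        "interaction_multiplier": m_inter,
        "n_crossing_fibers": max(0, int(round(spec.base_crossings * m_ien))),
        "n_near_vessels": max(0, int(round(spec.base_near_vessels * m_inter))),
    }


def _section_spec_for(spec: CohortSpec, planted: dict, seed: int) -> SectionSpec:
    radius = 5.0 * float(np.sqrt(planted["vessel_area_multiplier"]))
    vessels = tuple(
        VesselPlacement(radius_um=radius, distance_um=radius + 3.0)
        for _ in range(planted["n_near_vessels"])
    ) + tuple(
        VesselPlacement(radius_um=radius, distance_um=None, axis_ratio=1.3) for _ in range(6)
    )
    channels = dict(spec.section.channels)
    trka_model = channels.get("TrkA", ChannelModel(1500.0))
    channels["TrkA"] = dataclasses.replace(
        trka_model, fiber_mean=trka_model.fiber_mean * planted["trka_multiplier"]
    )
    return dataclasses.replace(
        spec.section,
        n_crossing_fibers=planted["n_crossing_fibers"],
        vessels=vessels,
        channels=channels,
        seed=seed,
    )


def iter_cohort(spec: CohortSpec):
    """Yield one :class:`SubjectRecord` at a time (memory-bounded)."""
    ss = np.random.SeedSequence(spec.master_seed)
    children = ss.spawn(len(spec.groups))
    for i, (group, child) in enumerate(zip(spec.groups, children)):
        rng = np.random.default_rng(child)
        planted = _draw_subject_effects(spec, group, rng)
        img_seeds = [
            int(s.generate_state(1)[0] % 2**31) for s in child.spawn(spec.images_per_subject)
        ]
        sections, truths = [], []
        for seed in img_seeds:
            section, truth = generate_section(_section_spec_for(spec, planted, seed))
            sections.append(section)
            truths.append(truth)
        yield SubjectRecord(
            subject_id=f"S{i:03d}", group=group, sections=sections, truths=truths,
            planted=planted,
        )


def draw_qst_from_norms(norms, n_subjects: int, seed, z_shifts=None, stratum: str = "all"):
    """Draw raw QST profiles from the norms' own distributions.

    ``z_shifts`` maps parameter -> shift in reference-SD units (applied in
    the analysis domain); without shifts the cohort is drawn from the
    reference distribution itself, so about 5% of values fall outside the
    95% reference intervals — a direct calibration property.
    """
    import pandas as pd

    from .clinical import LOG10_PARAMETERS, QST_PARAMETERS

    rng = np.random.default_rng(seed)
    z_shifts = z_shifts or {}
    data = {"subject": [f"S{i:03d}" for i in range(n_subjects)]}
    for param in QST_PARAMETERS:
        e = norms.lookup(param, stratum)
        v = rng.normal(e.mean + z_shifts.get(param, 0.0) * e.sd, e.sd, n_subjects)
        data[param] = np.power(10.0, v) if param in LOG10_PARAMETERS else v
    return pd.DataFrame(data)


def generate_ct_table(spec: CohortSpec, seed=None):
    """Tidy triplicate Ct table with planted group folds.

    Reference gene RPL13A around Ct 18; targets TrkA and NGF with baseline
    dCt of 8 and 7 cycles. A planted fold g in patients shifts the patient
    dCt by -log2(g). Replicate noise SD 0.12 cycles; subject dCt SD 0.25.
    """
    import pandas as pd

    rng = np.random.default_rng(
        seed if seed is not None else np.random.SeedSequence(spec.master_seed).spawn(1)[0]
    )
    base_dct = {"TrkA": 8.0, "NGF": 7.0}
    folds = {"TrkA": spec.trka_fold, "NGF": spec.ngf_fold}
    rows = []
    for i, group in enumerate(spec.groups):
        sample = f"S{i:03d}"
        ref_ct = rng.normal(18.0, 0.3)
        for rep in range(3):
            rows.append({"sample": sample, "group": group, "gene": "RPL13A",
                         "replicate": rep, "ct": ref_ct + rng.normal(0, 0.12)})
        for gene in ("TrkA", "NGF"):
            shift = -np.log2(folds[gene]) if group != "control" else 0.0
            dct = base_dct[gene] + shift + rng.normal(0, 0.25)
            for rep in range(3):
                rows.append({"sample": sample, "group": group, "gene": gene,
                             "replicate": rep, "ct": ref_ct + dct + rng.normal(0, 0.12)})
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, out_dir):
    """Write a full synthetic cohort to ``out_dir``.

    Emits, per subject, multi-channel TIFFs and label-mask TIFFs with YAML
    sidecars; cohort-level qst_raw.csv, ct_values.csv, subjects.csv and a
    truth_manifest.json recording every planted parameter. Returns the
    manifest dictionary. Fully reproducible from ``spec.master_seed``.
    """
    import json
    from pathlib import Path

    from . import io as nsio
    from .clinical import synthetic_norms

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": spec.master_seed, "subjects": []}
    subjects_rows = []
    for rec in iter_cohort(spec):
        sdir = out / rec.subject_id
        sdir.mkdir(exist_ok=True)
        entry = {"subject": rec.subject_id, "group": rec.group,
                 "planted": {k: float(v) for k, v in rec.planted.items()}, "images": []}
        for j, (section, truth) in enumerate(zip(rec.sections, rec.truths)):
            stem = f"{rec.subject_id}_img{j}"
            nsio.write_section(sdir / stem, section)
            entry["images"].append(
                {
                    "stem": stem,
                    "crossing_count": truth.crossing_count,
                    "membrane_length_mm": truth.membrane_length_mm,
                    "vessel_area_um2": truth.vessel_area_um2,
                    "interaction_area_um2": truth.interaction_area_um2,
                }
            )
        manifest["subjects"].append(entry)
        subjects_rows.append({"subject": rec.subject_id, "group": rec.group})
    import pandas as pd

    pd.DataFrame(subjects_rows).to_csv(out / "subjects.csv", index=False)
    ss = np.random.SeedSequence(spec.master_seed).spawn(2)
    norms = synthetic_norms()
    norms.to_yaml(out / "norms.yaml")
    qst = draw_qst_from_norms(norms, len(spec.groups), ss[0])
    qst["group"] = spec.groups
    qst.to_csv(out / "qst_raw.csv", index=False)
    generate_ct_table(spec, ss[1]).to_csv(out / "ct_values.csv", index=False)
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
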