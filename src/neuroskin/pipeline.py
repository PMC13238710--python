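"""Per-subject quantification and cohort-level reporting.

The per-image pipeline runs ROI derivation (50 um sub-epidermal band,
basement membrane), fiber-density counting, per-marker MFI within nerve
masks, and dermal vessel metrics at the 5 um proximity radius, producing
one tidy row per image plus a per-subject aggregate (arithmetic mean of
per-image metrics, missing values dropped).

The cohort layer runs the two contrast families — control vs all patients
and painless vs painful (plus each subgroup vs control) — routing every
metric through normality-based test selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fluorescence import area_ratio, mfi, normalized_mfi
from .ienfd import count_crossings, ienfd_density
from .masks import derive_rois
from .neurovascular import interaction_area
from .stats import ContingencyTable2x2, compare_groups

__all__ = [
    "RunConfig",
    "quantify_section",
    "run_subject",
    "quantify_cohort",
    "run_cohort",
    "score_qst_cohort",
    "qst_contingency",
]

logger = logging.getLogger(__name__)

CONTRASTS = (
    ("control", "bipn"),
    ("painless", "painful"),
    ("control", "painless"),
    ("control", "painful"),
)

_NON_METRIC_COLUMNS = {"subject", "image", "group", "proximity_radius_um"}


def _slug(marker: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in marker.lower())


@dataclass
class RunConfig:
    """Analysis constants and routing options.

    Defaults are the standard protocol constants: 50 um sub-epidermal
    expansion and 5 um vessel-nerve proximity radius.
    """

    expansion_um: float = 50.0
    proximity_radius_um: float = 5.0
    nerve_marker: str = "PGP9.5"
    reference_marker: str = "PGP9.5"
    mfi_markers: tuple = ("PGP9.5", "TrkA", "GAP43", "CGRP")
    mfi_rois: tuple = ("epidermis", "subepidermis")
    aggregation: str = "mean"
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = {
            "expansion_um": self.expansion_um,
            "proximity_radius_um": self.proximity_radius_um,
            "nerve_marker": self.nerve_marker,
            "reference_marker": self.reference_marker,
            "mfi_markers": list(self.mfi_markers),
            "mfi_rois": list(self.mfi_rois),
            "aggregation": self.aggregation,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["mfi_markers"] = tuple(data.get("mfi_markers", cls.mfi_markers))
        data["mfi_rois"] = tuple(data.get("mfi_rois", cls.mfi_rois))
        return cls(**data)


def quantify_section(section, config: RunConfig | None = None) -> dict:
    """All per-image metrics for one annotated section."""
    cfg = config or RunConfig()
    masks = section.masks
    rois = derive_rois(masks["epidermis"], masks["dermis"], cfg.expansion_um)
    nerve = masks["nerve"]
    row: dict = {"length_mm": rois.membrane.length_mm}

    crossings = count_crossings(nerve, rois)
    dens = ienfd_density(crossings, rois.membrane.length_mm, marker=cfg.nerve_marker)
    row["crossings_pgp9_5"] = crossings.count
    row["ienfd_pgp9_5"] = dens.fibers_per_mm
    row["nerve_area_epidermis_um2"] = nerve.intersect(rois.epidermis).area_um2

    if "cgrp" in masks:
        cgrp = masks["cgrp"]
        cg_cross = count_crossings(cgrp, rois)
        row["ienfd_cgrp"] = ienfd_density(
            cg_cross, rois.membrane.length_mm, marker="CGRP"
        ).fibers_per_mm
        row["cgrp_area_ratio_epidermis"] = area_ratio(cgrp, nerve, rois.epidermis)

    roi_masks = {"epidermis": rois.epidermis, "subepidermis": rois.subepidermis}
    for roi_name in cfg.mfi_rois:
        roi = roi_masks[roi_name]
        ref_rec = None
        if cfg.reference_marker in section.channels:
            ref_rec = mfi(section.channels[cfg.reference_marker], nerve, roi, roi_name)
        for marker in cfg.mfi_markers:
            if marker not in section.channels:
                continue
            rec = mfi(section.channels[marker], nerve, roi, roi_name)
            row[f"mfi_{_slug(marker)}_{roi_name}"] = rec.mfi
            if ref_rec is not None and marker != cfg.reference_marker:
                row[f"norm_mfi_{_slug(marker)}_{roi_name}"] = normalized_mfi(
                    rec, ref_rec
                ).normalized_mfi

    if "vessels" in masks:
        vm = interaction_area(masks["vessels"], nerve, masks["dermis"], cfg.proximity_radius_um)
        row["vessel_area_um2"] = vm.vessel_area_um2
        row["interaction_area_um2"] = vm.interaction_area_um2
        row["proximity_radius_um"] = vm.proximity_radius_um
    return row


def run_subject(subject_id: str, sections, config: RunConfig | None = None):
    """Quantify every image of one subject and aggregate.

    Returns (per-image rows, aggregate row). Aggregation is the arithmetic
    mean over images with missing values dropped per metric.
    """
    cfg = config or RunConfig()
    image_rows = []
    for j, section in enumerate(sections):
        row = {"subject": subject_id, "image": j}
        row.update(quantify_section(section, cfg))
        image_rows.append(row)
    frame = pd.DataFrame(image_rows)
    metric_cols = [c for c in frame.columns if c not in ("subject", "image")]
    agg = {"subject": subject_id, "image": "aggregate"}
    for c in metric_cols:
        agg[c] = float(frame[c].mean(skipna=True))
    return image_rows, agg


def quantify_cohort(subject_records, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-subject aggregated metrics for an iterable of subject records.

    Each record needs ``subject_id``, ``group`` and ``sections`` attributes
    (e.g. :class:`neuroskin.synthetic.SubjectRecord`). Subjects whose
    quantification fails are skipped with a logged reason.
    """
    rows = []
    for rec in subject_records:
        try:
            _, agg = run_subject(rec.subject_id, rec.sections, config)
        except ValueError as exc:
            logger.warning("skipping subject %s: %s", rec.subject_id, exc)
            continue
        agg["group"] = rec.group
        rows.append(agg)
    return pd.DataFrame(rows)


def _group_values(metrics: pd.DataFrame, metric: str, group: str) -> np.ndarray:
    if group == "bipn":
        sel = metrics["group"].isin(("painless", "painful"))
    else:
        sel = metrics["group"] == group
    return metrics.loc[sel, metric].dropna().to_numpy()


def run_cohort(metrics: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Group-comparison report over every metric column.

    ``metrics`` is the per-subject aggregated frame with a ``group`` column
    covering {control, painless, painful}. Contrasts with an absent group
    are skipped with a log entry.
    """
    if metrics is None or len(metrics) == 0:
        raise ValueError("empty metrics table: nothing to compare (run quantification first)")
    if "group" not in metrics.columns:
        raise ValueError("metrics table needs a 'group' column")
    metric_cols = [
        c for c in metrics.columns
        if c not in _NON_METRIC_COLUMNS and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    rows = []
    for metric in metric_cols:
        for ga, gb in CONTRASTS:
            x = _group_values(metrics, metric, ga)
            y = _group_values(metrics, metric, gb)
            if min(x.size, y.size) == 0:
                logger.info("contrast %s vs %s skipped for %s: empty group", ga, gb, metric)
                continue
            cmp = compare_groups(x, y)
            rows.append(
                {
                    "metric": metric,
                    "contrast": f"{ga}_vs_{gb}",
                    "route": cmp.route,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "n_a": cmp.x_desc.n,
                    "n_b": cmp.y_desc.n,
                    "mean_a": cmp.x_desc.mean,
                    "mean_b": cmp.y_desc.mean,
                    "median_a": cmp.x_desc.median,
                    "median_b": cmp.y_desc.median,
                    "iqr_a": cmp.x_desc.iqr,
                    "iqr_b": cmp.y_desc.iqr,
                    "note": cmp.note,
                }
            )
    return pd.DataFrame(rows)


def score_qst_cohort(qst: pd.DataFrame, norms, stratum_column: str | None = None) -> pd.DataFrame:
    """Score every subject's QST profile; tidy rows (subject, parameter, z, status)."""
    from .clinical import QST_PARAMETERS, score_profile

    frames = []
    for _, row in qst.iterrows():
        raw = {p: row[p] for p in QST_PARAMETERS if p in qst.columns}
        stratum = row[stratum_column] if stratum_column else "all"
        scored = score_profile(raw, norms, stratum=stratum)
        scored.insert(0, "subject", row.get("subject", ""))
        if "group" in qst.columns:
            scored["group"] = row["group"]
        frames.append(scored)
    return pd.concat(frames, ignore_index=True)


def qst_contingency(
    scored: pd.DataFrame,
    parameter: str,
    group_a: str = "painful",
    group_b: str = "painless",
) -> ContingencyTable2x2:
    """2x2 abnormality table for one parameter between two subgroups.

    Missing scores are excluded from the denominators.
    """
    sub = scored[(scored["parameter"] == parameter) & (scored["status"] != "missing")]
    a_rows = sub[sub["group"] == group_a]
    b_rows = sub[sub["group"] == group_b]
    return ContingencyTable2x2(
        a=int((a_rows["status"] == "abnormal").sum()),
        b=int((a_rows["status"] == "normal").sum()),
        c=int((b_rows["status"] == "abnormal").sum()),
        d=int((b_rows["status"] == "normal").sum()),
        row_labels=(group_a, group_b),
    )
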