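"""Relative gene expression by the Livak 2^-ddCt method.

Per sample: dCt = mean(Ct_target) - mean(Ct_reference) over replicates;
ddCt = dCt - mean(dCt over the calibrator group); fold = 2^-ddCt. The
calibrator-group baseline uses the arithmetic mean of calibrator dCt values
(standard Livak), which makes the geometric mean of calibrator-group fold
changes exactly 1.

Replicate aggregation is the arithmetic mean of Ct; a replicate SD above
0.5 cycles flags the (sample, gene) pair for QC. Samples missing the
reference gene are excluded and reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["fold_change", "REFERENCE_GENE", "REPLICATE_SD_FLAG"]

logger = logging.getLogger(__name__)

REFERENCE_GENE = "RPL13A"
REPLICATE_SD_FLAG = 0.5  # cycles


def _validate_ct(ct: pd.DataFrame) -> None:
    required = {"sample", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    bad = ct["ct"].dropna()
    if ((bad <= 0) | (bad > 40)).any():
        raise ValueError("Ct values must lie in (0, 40]")


def fold_change(
    ct: pd.DataFrame,
    target: str,
    calibrator_group: str,
    reference_gene: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold change of ``target`` against a calibrator group.

    Parameters
    ----------
    ct
        Tidy replicate-level table with columns ``sample``, ``gene``, ``ct``
        and ``group`` (one row per replicate well).
    target
        Target gene name (e.g. "TrkA" or "NGF").
    calibrator_group
        Group label whose mean dCt is the ddCt baseline (e.g. "control").
    reference_gene
        Housekeeping gene, default RPL13A.

    Returns one row per usable sample: mean Cts, dCt, ddCt, fold and a
    replicate-QC flag.
    """
    _validate_ct(ct)
    if "group" not in ct.columns:
        raise ValueError("Ct table needs a 'group' column for the calibrator baseline")

    sub = ct[ct["gene"].isin([target, reference_gene])].dropna(subset=["ct"])
    agg = (
        sub.groupby(["sample", "group", "gene"])["ct"]
        .agg(mean_ct="mean", sd_ct=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    wide = agg.pivot(index=["sample", "group"], columns="gene", values="mean_ct")
    sds = agg.pivot(index=["sample", "group"], columns="gene", values="sd_ct")

    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    if target not in wide.columns:
        raise ValueError(f"target gene {target!r} absent from Ct table")

    usable = wide[reference_gene].notna() & wide[target].notna()
    dropped = wide.index[~usable].get_level_values("sample").tolist()
    if dropped:
        logger.warning("excluding samples without usable reference/target Ct: %s", dropped)
    wide = wide[usable]
    sds = sds.loc[wide.index]

    out = wide.reset_index()[["sample", "group"]].copy()
    out["ct_target"] = wide[target].to_numpy()
    out["ct_reference"] = wide[reference_gene].to_numpy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    out["replicate_flag"] = (
        (sds[target].to_numpy() > REPLICATE_SD_FLAG)
        | (sds[reference_gene].to_numpy() > REPLICATE_SD_FLAG)
    )

    calib = out.loc[out["group"] == calibrator_group, "dct"]
    if calib.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no usable samples")
    baseline = float(calib.mean())
    out["ddct"] = out["dct"] - baseline
    out["fold"] = np.power(2.0, -out["ddct"])
    out.attrs["target"] = target
    out.attrs["calibrator_group"] = calibrator_group
    out.attrs["excluded_samples"] = dropped
    return out
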