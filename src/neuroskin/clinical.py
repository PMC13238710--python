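"""Quantitative sensory testing (QST) z-scores and clinical classification.

Implements the DFNS analysis conventions for the standard 11-parameter QST
battery (CDT, WDT, TSL, CPT, HPT, MDT, MPT, MPS, WUR, PPT, VDT):

* CDT, WDT, TSL, PPT, MPT, MPS, WUR, MDT and VDT are log10-transformed
  before scoring; CPT and HPT are scored in linear domain.
* z = sign * (domain(x) - reference mean) / reference SD, where the sign
  multiplier (+1/-1) orients every parameter so that positive z means gain
  of sensory function and negative z means loss of function.
* A raw value is abnormal when its domain value falls outside the stratum's
  95% reference interval; both tails count (hypo- and hypersensitivity).
  Boundary values are normal (closed interval). Missing values stay missing
  and are excluded from denominators.

Published normative tables are *not* bundled (they are licensed data);
reference norms are a user-supplied table with free-form age/sex stratum
keys. :func:`synthetic_norms` builds a synthetic table with the same schema
for testing and simulation.

The 0-10 numerical rating scale (NRS) for pain bands as: 0 none, 1-3 mild,
4-6 moderate, >=7 severe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QST_PARAMETERS",
    "LOG10_PARAMETERS",
    "NormEntry",
    "ReferenceNorms",
    "synthetic_norms",
    "to_domain",
    "z_score",
    "classify_reference_range",
    "nrs_category",
    "score_profile",
]

QST_PARAMETERS: tuple[str, ...] = (
    "CDT", "WDT", "TSL", "CPT", "HPT", "MDT", "MPT", "MPS", "WUR", "PPT", "VDT",
)

# parameters scored after log10 transformation; CPT and HPT stay linear
LOG10_PARAMETERS: frozenset = frozenset(
    {"CDT", "WDT", "TSL", "PPT", "MPT", "MPS", "WUR", "MDT", "VDT"}
)


@dataclass(frozen=True)
class NormEntry:
    """Reference statistics for one parameter in one age/sex stratum.

    ``mean``/``sd`` and the 95% reference interval bounds are all expressed
    in the analysis domain (log10 for the log-transformed parameters, linear
    otherwise). ``sign`` is +1 or -1 and orients the z-score so that
    positive means gain of function.
    """

    parameter: str
    mean: float
    sd: float
    sign: int
    ref_low: float
    ref_high: float
    stratum: str = "all"

    def __post_init__(self) -> None:
        if self.parameter not in QST_PARAMETERS:
            raise ValueError(f"unknown QST parameter {self.parameter!r}")
        if not self.sd > 0:
            raise ValueError(f"{self.parameter}: reference SD must be > 0")
        if self.sign not in (-1, 1):
            raise ValueError(f"{self.parameter}: sign must be +1 or -1")
        if not self.ref_low < self.ref_high:
            raise ValueError(f"{self.parameter}: reference interval must have low < high")


class ReferenceNorms:
    """Lookup table of :class:`NormEntry` keyed by (parameter, stratum).

    Lookups fall back to the ``"all"`` stratum when a specific stratum is
    absent, so coarse tables remain usable.
    """

    def __init__(self, entries) -> None:
        self._table: dict[tuple[str, str], NormEntry] = {}
        for e in entries:
            self._table[(e.parameter, e.stratum)] = e

    def lookup(self, parameter: str, stratum: str = "all") -> NormEntry:
        try:
            return self._table[(parameter, stratum)]
        except KeyError:
            try:
                return self._table[(parameter, "all")]
            except KeyError:
                raise KeyError(
                    f"no reference norms for parameter {parameter!r} "
                    f"(stratum {stratum!r} or 'all')"
                ) from None

    def entries(self):
        return list(self._table.values())

    @classmethod
    def from_yaml(cls, path) -> "ReferenceNorms":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(NormEntry(**row) for row in raw["norms"])

    def to_yaml(self, path) -> None:
        rows = [
            {
                "parameter": e.parameter,
                "stratum": e.stratum,
                "mean": float(e.mean),
                "sd": float(e.sd),
                "sign": int(e.sign),
                "ref_low": float(e.ref_low),
                "ref_high": float(e.ref_high),
            }
            for e in self.entries()
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"norms": rows}, fh, sort_keys=False)


# Plausible-magnitude synthetic reference statistics, one stratum, in the
# analysis domain. These are NOT published normative values; they exist so
# the scoring machinery is testable without licensed tables.
_SYNTHETIC_BASE: dict[str, tuple[float, float, int]] = {
    # parameter: (mean_in_domain, sd_in_domain, gain/loss sign)
    "CDT": (0.10, 0.20, -1),   # log10 deg C below baseline; larger = less sensitive
    "WDT": (0.45, 0.18, -1),
    "TSL": (0.60, 0.20, -1),
    "CPT": (12.0, 8.0, 1),     # deg C, linear
    "HPT": (44.0, 3.0, -1),    # deg C, linear
    "MDT": (0.45, 0.35, -1),   # log10 mN
    "MPT": (1.85, 0.35, -1),
    "MPS": (0.20, 0.45, 1),    # log10 pain rating
    "WUR": (0.35, 0.20, 1),
    "PPT": (2.55, 0.15, -1),   # log10 kPa
    "VDT": (0.90, 0.05, 1),    # log10 x/8 score
}


def synthetic_norms() -> ReferenceNorms:
    """Synthetic single-stratum reference table (schema-complete stand-in)."""
    entries = []
    for param, (mean, sd, sign) in _SYNTHETIC_BASE.items():
        entries.append(
            NormEntry(
                parameter=param,
                mean=mean,
                sd=sd,
                sign=sign,
                ref_low=mean - 1.959963984540054 * sd,
                ref_high=mean + 1.959963984540054 * sd,
            )
        )
    return ReferenceNorms(entries)


def to_domain(parameter: str, x: float) -> float:
    """Map a raw value into the parameter's analysis domain.

    Returns NaN for missing values and for non-positive values of
    log-transformed parameters (flagged missing rather than an error: such
    values occur in practice as instrument floor readings).
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    if parameter in LOG10_PARAMETERS:
        if x <= 0:
            return float("nan")
        return math.log10(x)
    return float(x)


def z_score(x: float, entry: NormEntry) -> float:
    """Signed z-score of a raw value against a reference stratum."""
    v = to_domain(entry.parameter, x)
    if math.isnan(v):
        return float("nan")
    return entry.sign * (v - entry.mean) / entry.sd


def classify_reference_range(x: float, ref_low: float, ref_high: float) -> str:
    """Classify a domain value against a 95% reference interval.

    Closed interval: boundary values are normal. Both tails are abnormal
    (sensitivity as well as insensitivity). Missing stays ``"missing"``.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "missing"
    if x < ref_low or x > ref_high:
        return "abnormal"
    return "normal"


def nrs_category(max_nrs_last_week: int, relief_adjusted: float | None = None) -> str:
    """Band a 0-10 pain rating: none / mild / moderate / severe.

    When a medication-relief-adjusted rating is supplied it takes precedence
    over the raw maximum (the adjustment itself is performed upstream).
    """
    value = max_nrs_last_week if relief_adjusted is None else relief_adjusted
    if not 0 <= value <= 10:
        raise ValueError(f"NRS must be within 0-10, got {value}")
    if value == 0:
        return "none"
    if value <= 3:
        return "mild"
    if value <= 6:
        return "moderate"
    return "severe"


def score_profile(raw, norms: ReferenceNorms, stratum: str = "all") -> pd.DataFrame:
    """Score a subject's raw QST profile.

    Parameters
    ----------
    raw
        Mapping of parameter name -> raw value (missing values as NaN or
        simply absent).
    norms, stratum
        Reference table and the subject's age/sex stratum key.

    Returns a tidy frame with one row per parameter: raw value, domain
    value, z-score, abnormal flag and gain/loss direction.
    """
    rows = []
    for param in QST_PARAMETERS:
        x = raw.get(param, float("nan"))
        entry = norms.lookup(param, stratum)
        v = to_domain(param, x)
        z = z_score(x, entry)
        flag = classify_reference_range(v, entry.ref_low, entry.ref_high)
        direction = "missing" if math.isnan(z) else ("gain" if z > 0 else "loss" if z < 0 else "reference")
        rows.append(
            {
                "parameter": param,
                "raw": x,
                "domain_value": v,
                "z": z,
                "status": flag,
                "direction": direction,
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)
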