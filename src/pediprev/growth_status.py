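"""BMI, LMS z-scores, weight-status classification and plausibility filtering.

The weight-status categories follow the convention used in pediatric
growth surveillance: BMI-for-age z-scores against a sex/age growth
reference parameterized by the LMS method (Box-Cox power ``L``, median
``M``, coefficient of variation ``S``), cut at -2, +1 and +2 SD.  Two
labelling schemes exist for the same cut points:

* ``young`` (ages 2-5): underweight / normal / at risk of overweight /
  overweight-obese;
* ``older`` (above 5): underweight / normal / overweight / obese.

Records with |z| >= 5 are treated as implausible (data-entry artifacts)
and excluded before any prevalence estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthReferenceRow",
    "YOUNG_LABELS",
    "OLDER_LABELS",
    "Z_CUTOFFS",
    "Z_PLAUSIBLE_LIMIT",
    "bmi",
    "lms_zscore",
    "lms_value",
    "classify",
    "category_index",
    "filter_implausible",
    "load_lms_reference",
    "zscore_from_reference",
    "synthetic_lms_table",
]

#: category boundaries on the z scale, shared by both labelling schemes
Z_CUTOFFS = (-2.0, 1.0, 2.0)

#: |z| at or beyond this value is considered a data-entry artifact
Z_PLAUSIBLE_LIMIT = 5.0

YOUNG_LABELS = ("underweight", "normal", "at_risk", "overweight_obese")
OLDER_LABELS = ("underweight", "normal", "overweight", "obese")

_SCHEME_LABELS = {"young": YOUNG_LABELS, "older": OLDER_LABELS}


@dataclass(frozen=True)
class GrowthReferenceRow:
    """LMS parameters for one sex/age stratum of a growth reference."""

    sex: str
    age_months: int
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0 or self.S <= 0:
            raise ValueError(f"M and S must be positive, got M={self.M}, S={self.S}")


def bmi(weight_kg, height_m):
    """Body mass index: weight in kilograms divided by height in meters squared."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight_kg and height_m must be strictly positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def lms_zscore(value, L: float, M: float, S: float):
    """LMS z-score ``((value/M)**L - 1) / (L*S)``.

    Continuous at L = 0 where the Box-Cox transform degenerates to the
    log form ``ln(value/M) / S``; the log form is used for |L| < 1e-8.
    """
    value = np.asarray(value, dtype=float)
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be positive")
    if np.any(value <= 0):
        raise ValueError("value must be strictly positive")
    if abs(L) < 1e-8:
        z = np.log(value / M) / S
    else:
        z = ((value / M) ** L - 1.0) / (L * S)
    return float(z) if z.ndim == 0 else z


def lms_value(z, L: float, M: float, S: float):
    """Inverse of :func:`lms_zscore`: the measurement at a given z-score."""
    z = np.asarray(z, dtype=float)
    if abs(L) < 1e-8:
        v = M * np.exp(S * z)
    else:
        v = M * (1.0 + L * S * z) ** (1.0 / L)
    return float(v) if v.ndim == 0 else v


def category_index(z):
    """Map z to the category index 0..3 (shared cut points of both schemes).

    Boundary convention: -2 and +1 belong to ``normal``, +2 to the third
    category (at risk / overweight); only strictly above +2 is the
    fourth category (overweight-obese / obese).
    """
    z = np.asarray(z, dtype=float)
    c1, c2, c3 = Z_CUTOFFS
    idx = np.select([z < c1, z <= c2, z <= c3], [0, 1, 2], default=3)
    return int(idx) if idx.ndim == 0 else idx


def classify(z, scheme: str = "young"):
    """Weight-status label(s) for z-score(s) under the given age scheme."""
    try:
        labels = _SCHEME_LABELS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected 'young' or 'older'") from None
    idx = category_index(z)
    if np.isscalar(idx):
        return labels[idx]
    return np.take(np.asarray(labels, dtype=object), idx)


def filter_implausible(
    records: pd.DataFrame, columns: Sequence[str] = ("z_base", "z_follow")
) -> tuple[pd.DataFrame, int]:
    """Drop records whose z-score is at or beyond +/-5 SD.

    Missing z values are left untouched (missingness is handled by the
    estimators, not by this filter).  Returns the kept records and the
    number excluded, for the study flowchart log.
    """
    cols = [c for c in columns if c in records.columns]
    if not cols or records.empty:
        return records, 0
    bad = pd.Series(False, index=records.index)
    for c in cols:
        z = pd.to_numeric(records[c], errors="coerce")
        bad |= z.abs().ge(Z_PLAUSIBLE_LIMIT).fillna(False)
    return records.loc[~bad], int(bad.sum())


def load_lms_reference(path) -> pd.DataFrame:
    """Read an LMS reference table (CSV columns sex, age_months, L, M, S)."""
    table = pd.read_csv(path)
    required = {"sex", "age_months", "L", "M", "S"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"LMS reference missing columns: {sorted(missing)}")
    if (table["M"] <= 0).any() or (table["S"] <= 0).any():
        raise ValueError("LMS reference contains non-positive M or S")
    return table


def zscore_from_reference(value: float, sex: str, age_months: int, table: pd.DataFrame) -> float:
    """z-score of a BMI value against the matching sex/age reference row."""
    row = table[(table["sex"] == sex) & (table["age_months"] == age_months)]
    if row.empty:
        raise KeyError(f"no LMS reference row for sex={sex!r}, age_months={age_months}")
    r = row.iloc[0]
    return lms_zscore(value, float(r["L"]), float(r["M"]), float(r["S"]))


def synthetic_lms_table(age_months: Iterable[int] = range(24, 181, 6)) -> pd.DataFrame:
    """A synthetic LMS reference for tests and examples.

    Smooth, plausible-looking L/M/S curves (median BMI dipping around age
    5-6 then rising, mild negative skew).  These are constructed values
    for exercising the z-score machinery, not any published growth
    standard.
    """
    rows = []
    for sex, m_shift in (("boy", 0.0), ("girl", -0.2)):
        for a in age_months:
            years = a / 12.0
            rows.append(
                GrowthReferenceRow(
                    sex=sex,
                    age_months=int(a),
                    L=-1.2 - 0.004 * (a - 24),
                    M=15.5 + m_shift + 0.03 * (years - 6.0) ** 2,
                    S=0.08 + 0.0003 * (a - 24),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
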