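"""End-to-end orchestration: cohort I/O, coverage reporting, comparison.

The cohort CSV is wide, one row per child:

    child_id, sex{boy,girl}, residence{rural,urban}, income{1,2,3,4},
    z_base, status_base, age_years, measured{0,1}, z_follow (empty iff
    unmeasured), status_follow (empty iff unmeasured)

Measurement events (used only by the coverage table) are long:

    child_id, date (ISO-8601), weight_kg, height_m

A child counts as *measured* in a window only when a single event
carries both weight and height — the same-time-point rule of pediatric
EHR surveillance.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import complete_case_prevalence, ipw_prevalence
from .growth_status import OLDER_LABELS, YOUNG_LABELS, filter_implausible
from .imputation import mi_prevalence
from .missingness_ipw import fit_missingness, stabilized_weights
from .reference_tables import SCHEDULED_AGES

__all__ = [
    "CohortValidationError",
    "percent",
    "coverage_table",
    "coverage_from_counts",
    "read_cohort",
    "write_cohort",
    "run_comparison",
]

log = logging.getLogger("pediprev")

_COLUMNS = [
    "child_id",
    "sex",
    "residence",
    "income",
    "z_base",
    "status_base",
    "age_years",
    "measured",
    "z_follow",
    "status_follow",
]


class CohortValidationError(ValueError):
    """Schema violation in a cohort CSV, with the offending row number."""


def percent(n: float, total: float) -> float:
    """Percentage to one decimal, the convention of coverage tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n / total, 1)


def coverage_table(
    events: pd.DataFrame,
    population: pd.DataFrame,
    window_1y: tuple[str, str],
    window_4y: tuple[str, str],
) -> pd.DataFrame:
    """Per-age measurement coverage in a one-year and a four-year window.

    ``events`` columns: child_id, date, weight_kg, height_m (NaN when a
    component is absent); ``population`` columns: child_id, age_years.
    A child is measured in a window iff at least one event inside it has
    both weight and height.
    """
    unknown = set(events["child_id"]) - set(population["child_id"])
    if unknown:
        raise CohortValidationError(
            f"events reference unknown children: {sorted(unknown)[:5]}"
        )
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    complete = ev[ev["weight_kg"].notna() & ev["height_m"].notna()]

    def measured_ids(window):
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        inside = complete[(complete["date"] >= lo) & (complete["date"] <= hi)]
        return set(inside["child_id"])

    ids_1y, ids_4y = measured_ids(window_1y), measured_ids(window_4y)
    rows = []
    for age, group in population.groupby("age_years"):
        ids = set(group["child_id"])
        n_total = len(ids)
        n1 = len(ids & ids_1y)
        n4 = len(ids & ids_4y)
        rows.append(
            {
                "age_years": int(age),
                "n_total": n_total,
                "n_measured_1y": n1,
                "pct_1y": percent(n1, n_total),
                "n_measured_4y": n4,
                "pct_4y": percent(n4, n_total),
                "scheduled_visit": int(age) in SCHEDULED_AGES,
            }
        )
    return pd.DataFrame(rows).sort_values("age_years", ignore_index=True)


def coverage_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Coverage percentages (and a totals row) from per-age count data.

    ``counts`` columns: age_years, n_total, n_measured_1y, n_measured_4y.
    """
    out = counts.copy()
    out["pct_1y"] = [percent(n, t) for n, t in zip(out["n_measured_1y"], out["n_total"])]
    out["pct_4y"] = [percent(n, t) for n, t in zip(out["n_measured_4y"], out["n_total"])]
    out["scheduled_visit"] = [a in SCHEDULED_AGES for a in out["age_years"]]
    total = {
        "age_years": -1,
        "n_total": int(out["n_total"].sum()),
        "n_measured_1y": int(out["n_measured_1y"].sum()),
        "n_measured_4y": int(out["n_measured_4y"].sum()),
        "scheduled_visit": False,
    }
    total["pct_1y"] = percent(total["n_measured_1y"], total["n_total"])
    total["pct_4y"] = percent(total["n_measured_4y"], total["n_total"])
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write the wide cohort CSV; follow-up fields blank for unmeasured."""
    out = records.copy()
    measured = out["measured"].astype(bool)
    out["measured"] = measured.astype(int)
    out.loc[~measured, "z_follow"] = np.nan
    out.loc[~measured, "status_follow"] = ""
    out[_COLUMNS].to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (round-trips with write_cohort)."""
    df = pd.read_csv(path, dtype={"child_id": str, "status_follow": str})
    missing_cols = set(_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"missing columns: {sorted(missing_cols)}")
    if df.empty:
        return df[_COLUMNS]

    def bad_rows(mask) -> str:
        # +2: header line plus 1-based numbering
        return ", ".join(str(i + 2) for i in df.index[mask][:5])

    checks = [
        ("sex", ~df["sex"].isin(["boy", "girl"]), "sex must be boy/girl"),
        ("residence", ~df["residence"].isin(["rural", "urban"]), "residence must be rural/urban"),
        ("income", ~df["income"].isin([1, 2, 3, 4]), "income must be 1..4"),
        (
            "status_base",
            ~df["status_base"].isin(YOUNG_LABELS),
            f"status_base must be one of {YOUNG_LABELS}",
        ),
        ("measured", ~df["measured"].isin([0, 1]), "measured must be 0/1"),
    ]
    for col, mask, msg in checks:
        if mask.any():
            raise CohortValidationError(f"{msg} (rows {bad_rows(mask)})")
    for col in ("z_base", "z_follow"):
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if mask.any():
            raise CohortValidationError(f"non-numeric {col} (rows {bad_rows(mask)})")
        df[col] = vals
    measured = df["measured"].astype(bool)
    mask = measured & df["z_follow"].isna()
    if mask.any():
        raise CohortValidationError(f"measured children lack z_follow (rows {bad_rows(mask)})")
    mask = measured & ~df["status_follow"].isin(OLDER_LABELS)
    if mask.any():
        raise CohortValidationError(
            f"status_follow must be one of {OLDER_LABELS} for measured children "
            f"(rows {bad_rows(mask)})"
        )
    df["measured"] = measured
    df.loc[~measured, "status_follow"] = pd.NA
    return df[_COLUMNS]


def run_comparison(
    cohort: pd.DataFrame,
    seed: int = 0,
    m_imputations: int = 10,
    methods: Sequence[str] = ("complete_case", "ipw", "mi"),
    ci_method: str = "logit",
    ridge: float = 0.0,
) -> pd.DataFrame:
    """Three-estimator prevalence comparison on one cohort.

    Applies the plausibility filter, fits the missingness model once,
    and returns a long table (method x category) of estimates with 95%
    CIs.  Deterministic given (cohort, seed).  ``ridge`` adds a weak
    Gaussian prior to the missingness fit — useful for small samples
    where a rare covariate level can be separated.
    """
    filtered, n_excluded = filter_implausible(cohort)
    if n_excluded:
        log.info("plausibility filter removed %d record(s) with |z| >= 5", n_excluded)

    tables: list[pd.DataFrame] = []
    if "complete_case" in methods:
        tables.append(complete_case_prevalence(filtered, ci_method=ci_method))
    if "ipw" in methods:
        if filtered["measured"].astype(bool).all():
            # no missing data: the stabilized weights are identically 1
            tables.append(
                complete_case_prevalence(filtered, ci_method=ci_method).assign(method="ipw")
            )
        else:
            fit = fit_missingness(filtered, ridge=ridge)
            sw = stabilized_weights(fit, filtered)
            log.info(
                "stabilized weights: mean %.4f, sd %.4f, numerator %.4f",
                sw.mean,
                sw.sd,
                sw.numerator_prob,
            )
            tables.append(ipw_prevalence(filtered, sw, ci_method=ci_method))
    if "mi" in methods:
        log.info("MI with m=%d imputations, seed %d", m_imputations, seed)
        tables.append(mi_prevalence(filtered, m=m_imputations, seed=seed))
    if not tables:
        raise ValueError(f"no known methods among {methods!r}")
    return pd.concat(tables, ignore_index=True)


def age_standard_weights(cohort: pd.DataFrame) -> Mapping[int, float]:
    """Full-cohort age distribution — the internal standard for adjustment."""
    counts = cohort["age_years"].value_counts().sort_index()
    return {int(a): float(c) / len(cohort) for a, c in counts.items()}
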