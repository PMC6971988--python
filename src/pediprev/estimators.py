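"""Prevalence estimators: complete-case, stabilized-IPW and age-adjusted.

All four weight-status categories are estimated jointly from one set of
multinomial indicators, which enforces the sum-to-one constraint by
construction.  Variances are linearized (Horvitz-Thompson style,
weights treated as fixed, survey ``pweight`` convention) with a finite
sample factor n/(n-1); confidence intervals are Wald on the logit scale
back-transformed, which keeps them inside (0, 1) — a plain Wald CI is
available via ``ci_method="wald"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .growth_status import OLDER_LABELS
from .missingness_ipw import StabilizedWeightSet

__all__ = [
    "PrevalenceEstimate",
    "weighted_prevalence",
    "complete_case_prevalence",
    "ipw_prevalence",
    "age_adjusted_prevalence",
]

_Z975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """One category's prevalence with variance and 95% CI."""

    method: str
    category: str
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    n_effective: float


def _interval(p: float, var: float, ci_method: str) -> tuple[float, float]:
    if var < 0:
        raise ValueError("variance must be non-negative")
    se = np.sqrt(var)
    if ci_method == "wald":
        return max(0.0, p - _Z975 * se), min(1.0, p + _Z975 * se)
    if ci_method != "logit":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if p <= 0.0 or p >= 1.0 or se == 0.0:
        # degenerate proportion: the logit transform is undefined; clamp
        return float(np.clip(p, 0, 1)), float(np.clip(p, 0, 1))
    se_logit = se / (p * (1.0 - p))
    return float(expit(logit(p) - _Z975 * se_logit)), float(expit(logit(p) + _Z975 * se_logit))


def _as_table(estimates: Sequence[PrevalenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def weighted_prevalence(
    statuses: Sequence,
    weights=None,
    categories: Sequence[str] = OLDER_LABELS,
    method: str = "complete_case",
    ci_method: str = "logit",
) -> pd.DataFrame:
    """Joint (weighted) prevalence of the four categories.

    ``p_c = sum(w*y_c) / sum(w)`` with linearized variance
    ``n/(n-1) * sum(w^2 (y_c - p_c)^2) / (sum w)^2``; with unit weights
    this reduces to ``p(1-p)/(n-1)``.
    """
    statuses = np.asarray(statuses, dtype=object)
    n = len(statuses)
    if n == 0:
        raise ValueError("no observed statuses to estimate from")
    unknown = set(statuses) - set(categories)
    if unknown:
        raise ValueError(f"statuses outside the category set: {sorted(map(str, unknown))}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("weights must align one-to-one with statuses")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    fpc = n / (n - 1) if n > 1 else 1.0
    n_eff = wsum**2 / np.sum(w**2)

    out = []
    for cat in categories:
        y = (statuses == cat).astype(float)
        p = float(np.sum(w * y) / wsum)
        var = float(fpc * np.sum((w * (y - p)) ** 2) / wsum**2)
        lo, hi = _interval(p, var, ci_method)
        out.append(
            PrevalenceEstimate(
                method=method,
                category=str(cat),
                estimate=p,
                variance=var,
                ci_low=lo,
                ci_high=hi,
                n_effective=float(n_eff),
            )
        )
    return _as_table(out)


def complete_case_prevalence(
    records: pd.DataFrame,
    categories: Sequence[str] = OLDER_LABELS,
    ci_method: str = "logit",
) -> pd.DataFrame:
    """Prevalence among measured children only (unweighted)."""
    measured = records[records["measured"].astype(bool)]
    if measured.empty:
        raise ValueError("no measured children; complete-case estimate undefined")
    return weighted_prevalence(
        measured["status_follow"].to_numpy(),
        categories=categories,
        method="complete_case",
        ci_method=ci_method,
    )


def ipw_prevalence(
    records: pd.DataFrame,
    weight_set: StabilizedWeightSet,
    categories: Sequence[str] = OLDER_LABELS,
    ci_method: str = "logit",
) -> pd.DataFrame:
    """Stabilized-IPW prevalence over the measured children."""
    measured = records[records["measured"].astype(bool)]
    w = weight_set.weights.reindex(measured.index)
    if w.isna().any():
        raise ValueError("weights do not cover every measured record")
    return weighted_prevalence(
        measured["status_follow"].to_numpy(),
        weights=w.to_numpy(),
        categories=categories,
        method="ipw",
        ci_method=ci_method,
    )


def age_adjusted_prevalence(
    per_age_estimates: Mapping[int, pd.DataFrame],
    standard_age_weights: Mapping[int, float],
    ci_method: str = "logit",
) -> pd.DataFrame:
    """Direct standardization over age strata.

    ``p_adj = sum_a pi_a p_a`` with ``var = sum_a pi_a^2 var_a``; the
    standard weights ``pi_a`` must cover every age and sum to 1.
    """
    ages = sorted(standard_age_weights)
    pi = np.asarray([standard_age_weights[a] for a in ages], dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("standard age weights must sum to 1")
    missing = [a for a in ages if a not in per_age_estimates]
    if missing:
        raise ValueError(f"missing per-age estimates for ages: {missing}")

    first = per_age_estimates[ages[0]]
    categories = list(first["category"])
    method = str(first["method"].iloc[0])
    out = []
    for cat in categories:
        p_a = np.empty(len(ages))
        v_a = np.empty(len(ages))
        neff = 0.0
        for i, a in enumerate(ages):
            row = per_age_estimates[a].set_index("category").loc[cat]
            p_a[i], v_a[i] = float(row["estimate"]), float(row["variance"])
            neff += float(row["n_effective"])
        p = float(pi @ p_a)
        var = float(pi**2 @ v_a)
        lo, hi = _interval(p, var, ci_method)
        out.append(
            PrevalenceEstimate(
                method=method,
                category=cat,
                estimate=p,
                variance=var,
                ci_low=lo,
                ci_high=hi,
                n_effective=neff,
            )
        )
    return _as_table(out)
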