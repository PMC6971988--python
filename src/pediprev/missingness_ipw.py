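"""Missingness model and stabilized inverse-probability weights.

``fit_missingness`` regresses the measured / not-measured flag on the
four observed covariates (logistic MLE via statsmodels) and reports
adjusted odds ratios with Wald 95% CIs in the layout of an
epidemiological "characteristics of measured vs non-measured" table.

``stabilized_weights`` builds the weights

    SW_i = P(measured) / P(measured | x_i)

for each measured child: the numerator is the unconditional empirical
measured fraction (taken directly from the data, no model) and the
denominator the fitted probability from the logistic model.  Stabilized
weights average ~1, so the weighted pseudo-population has (almost) the
size of the measured sample while representing the full cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from ._newton import penalized_multinomial
from .synthetic_cohort import INDICATOR_NAMES, indicator_matrix

__all__ = [
    "MissingnessFit",
    "StabilizedWeightSet",
    "DegenerateOutcomeError",
    "SeparationError",
    "PositivityError",
    "fit_missingness",
    "stabilized_weights",
    "DEFAULT_PREDICTORS",
]

#: covariate -> indicator (dummy) columns, reference levels boy / normal
#: weight / income "<18k" / rural
_PREDICTOR_DUMMIES = {
    "sex": ("sex_girl",),
    "status_base": ("base_underweight", "base_at_risk", "base_overweight_obese"),
    "income": ("income_basic", "income_mid", "income_high"),
    "residence": ("res_urban",),
}

DEFAULT_PREDICTORS = ("sex", "status_base", "income", "residence")

#: table row layout (covariate, level, indicator or None for reference)
_TABLE_ROWS = (
    ("sex", "boy", None),
    ("sex", "girl", "sex_girl"),
    ("status_base", "underweight", "base_underweight"),
    ("status_base", "normal", None),
    ("status_base", "at_risk", "base_at_risk"),
    ("status_base", "overweight_obese", "base_overweight_obese"),
    ("income", 1, "income_basic"),
    ("income", 2, None),
    ("income", 3, "income_mid"),
    ("income", 4, "income_high"),
    ("residence", "rural", None),
    ("residence", "urban", "res_urban"),
)


class DegenerateOutcomeError(ValueError):
    """All children measured (or none) — the logistic model is undefined."""


class SeparationError(RuntimeError):
    """Perfect separation: some covariate level predicts the outcome exactly."""


class PositivityError(RuntimeError):
    """A fitted measurement probability is (numerically) zero."""


@dataclass
class MissingnessFit:
    """Fitted measured/not-measured logistic model."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    or_table: pd.DataFrame
    n_measured: int
    n_total: int
    converged: bool

    def odds_ratio(self, indicator: str) -> float:
        return float(np.exp(self.coefficients[indicator]))

    def or_ci(self, indicator: str, level: float = 0.95) -> tuple[float, float]:
        q = norm.ppf(0.5 + level / 2)
        se = float(np.sqrt(self.covariance.loc[indicator, indicator]))
        b = float(self.coefficients[indicator])
        return float(np.exp(b - q * se)), float(np.exp(b + q * se))


@dataclass
class StabilizedWeightSet:
    """Stabilized weights for the measured children."""

    weights: pd.Series  # indexed by the measured rows of the cohort frame
    numerator_prob: float
    denominator_probs: pd.Series  # fitted P(measured | x) for every child

    @property
    def mean(self) -> float:
        return float(self.weights.mean())

    @property
    def sd(self) -> float:
        return float(self.weights.std(ddof=1))


def _design(records: pd.DataFrame, predictors) -> pd.DataFrame:
    names: list[str] = []
    for p in predictors:
        if p in _PREDICTOR_DUMMIES:
            names.extend(_PREDICTOR_DUMMIES[p])
        elif p in INDICATOR_NAMES:
            names.append(p)
        else:
            raise KeyError(f"unknown predictor {p!r}")
    X = indicator_matrix(records, names=tuple(names))
    return sm.add_constant(X, has_constant="add")


def fit_missingness(
    records: pd.DataFrame, predictors=DEFAULT_PREDICTORS, ridge: float = 0.0
) -> MissingnessFit:
    """Logistic fit of measured ~ covariates.

    By default a plain maximum-likelihood fit (matching standard
    statistical software).  ``ridge > 0`` adds a weak Gaussian prior of
    that precision on the slopes, useful for small per-age samples
    where a rare covariate level can have zero not-measured children
    and the MLE does not exist.

    Raises :class:`DegenerateOutcomeError` when the outcome has a single
    class and :class:`SeparationError` (naming the worst covariate) when
    the MLE diverges.
    """
    y = records["measured"].astype(int).to_numpy()
    n_total = len(y)
    n_measured = int(y.sum())
    if n_measured == 0 or n_measured == n_total:
        raise DegenerateOutcomeError(
            f"outcome is degenerate: {n_measured} measured of {n_total} children"
        )
    X = _design(records, predictors)

    if ridge > 0:
        penalize = np.asarray([0.0 if c == "const" else 1.0 for c in X.columns])
        beta, cov_arr, converged = penalized_multinomial(
            X.to_numpy(), y, 2, ridge, penalize
        )
        if not converged:
            raise SeparationError("penalized logistic fit did not converge")
        params = pd.Series(beta[:, 0], index=X.columns)
        cov = pd.DataFrame(cov_arr, index=X.columns, columns=X.columns)
        fit = MissingnessFit(
            coefficients=params,
            covariance=cov,
            or_table=pd.DataFrame(),
            n_measured=n_measured,
            n_total=n_total,
            converged=True,
        )
        fit.or_table = _or_table(records, fit)
        return fit

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is detected below
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError:
        raise SeparationError(
            f"logistic fit failed; suspected separation on {_separation_suspect(X, y)!r}"
        ) from None
    params = res.params
    slopes = params.drop("const")
    if (not res.mle_retvals.get("converged", False)) or (
        len(slopes) and slopes.abs().max() > 15
    ):
        worst = slopes.abs().idxmax() if len(slopes) else "const"
        raise SeparationError(
            f"logistic fit did not converge; suspected separation on {worst!r}"
        )

    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    fit = MissingnessFit(
        coefficients=params,
        covariance=cov,
        or_table=pd.DataFrame(),
        n_measured=n_measured,
        n_total=n_total,
        converged=True,
    )
    fit.or_table = _or_table(records, fit)
    return fit


def _separation_suspect(X: pd.DataFrame, y: np.ndarray) -> str:
    """Name the dummy column with an empty outcome cell, if any."""
    for col in X.columns:
        if col == "const":
            continue
        x = X[col].to_numpy() > 0
        for level in (x, ~x):
            if level.any() and (y[level].min() == y[level].max()):
                return col
    return "unknown"


def _or_table(records: pd.DataFrame, fit: MissingnessFit) -> pd.DataFrame:
    """Adjusted-OR table in the published layout (reference rows OR = 1)."""
    measured = records["measured"].astype(bool)
    rows = []
    for covariate, level, indicator in _TABLE_ROWS:
        if covariate not in records.columns:
            continue
        sel = records[covariate] == level
        n_tot = int(sel.sum())
        n_meas = int((sel & measured).sum())
        if indicator is None:
            or_, lo, hi = 1.0, np.nan, np.nan
        elif indicator in fit.coefficients.index:
            or_ = fit.odds_ratio(indicator)
            lo, hi = fit.or_ci(indicator)
        else:
            continue
        rows.append(
            {
                "covariate": covariate,
                "level": level,
                "n_total": n_tot,
                "n_measured": n_meas,
                "pct_measured": round(100.0 * n_meas / n_tot, 1) if n_tot else np.nan,
                "n_not_measured": n_tot - n_meas,
                "pct_not_measured": round(100.0 * (n_tot - n_meas) / n_tot, 1)
                if n_tot
                else np.nan,
                "odds_ratio": or_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def stabilized_weights(
    fit: MissingnessFit, records: pd.DataFrame, predictors=DEFAULT_PREDICTORS
) -> StabilizedWeightSet:
    """Stabilized weights ``SW_i = f(measured) / f(measured | x_i)``.

    ``records`` must be the full cohort (measured and not); weights are
    defined for the measured children only.
    """
    if not fit.converged:
        raise SeparationError("cannot build weights from a non-converged fit")
    X = _design(records, predictors)
    X = X[fit.coefficients.index]  # align column order with the fit
    p_hat = pd.Series(
        expit(X.to_numpy() @ fit.coefficients.to_numpy()), index=records.index
    )
    measured = records["measured"].astype(bool)
    if (p_hat[measured] < 1e-6).any():
        raise PositivityError(
            "fitted measurement probability below 1e-6 for a measured child "
            "(positivity violation)"
        )
    numerator = fit.n_measured / fit.n_total
    weights = numerator / p_hat[measured]
    return StabilizedWeightSet(
        weights=weights, numerator_prob=numerator, denominator_probs=p_hat
    )
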