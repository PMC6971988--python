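"""Multiple imputation of missing weight status and Rubin's-rules pooling.

The follow-up weight status (a 4-level category) is imputed directly
from a multinomial-logistic model on the four observed covariates,
fitted on the measured children.  Imputation is *proper*: for each of
the ``m`` imputations a parameter vector is drawn from the asymptotic
normal posterior MVN(beta_hat, V_hat) before category probabilities are
computed and categories sampled, so between-imputation variance
reflects model uncertainty as well as sampling noise.  Pooling follows
Rubin's rules: pooled point estimate = mean, total variance = within +
(1 + 1/m) x between, t reference with the classic large-sample degrees
of freedom.

The multinomial fit is a MAP estimate under a weak Gaussian prior on
the slope coefficients (ridge penalty, default precision 0.16,
i.e. prior SD 2.5 on the log-odds scale, the usual weakly-informative
choice for logistic models).  Realistic cohorts have structurally
sparse cells — e.g. no underweight follow-ups among children who were
at risk of overweight at baseline — where the unpenalized MLE diverges
(quasi-separation); the prior bounds those log-odds (and, critically,
their posterior spread, which otherwise inflates the proper-imputation
draws) without materially shrinking well-identified coefficients.  Intercepts
are never penalized, so an intercept-only model reproduces the observed
category frequencies exactly.  ``ridge=0`` gives the plain MLE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import weighted_prevalence
from .growth_status import OLDER_LABELS
from ._newton import penalized_multinomial
from .missingness_ipw import DEFAULT_PREDICTORS, SeparationError, _design

__all__ = [
    "ImputationModel",
    "ImputationResult",
    "PooledEstimate",
    "EmptyCategoryError",
    "fit_imputation_model",
    "draw_imputations",
    "rubin_pool",
    "mi_prevalence",
]

#: outcome coding for the multinomial fit — normal weight is the baseline
_OUTCOME_ORDER = ("normal", "underweight", "overweight", "obese")


class EmptyCategoryError(ValueError):
    """An outcome category has no measured children; the model cannot fit it."""


@dataclass
class ImputationModel:
    """Fitted multinomial-logistic imputation model."""

    params: np.ndarray  # (p, K-1), column j -> category _OUTCOME_ORDER[j+1]
    covariance: np.ndarray  # ((K-1)*p, (K-1)*p), params stacked column-wise
    exog_names: tuple[str, ...]
    categories: tuple[str, ...]
    predictors: tuple[str, ...]
    converged: bool


@dataclass
class ImputationResult:
    """``m`` completed status vectors over all children."""

    m: int
    completed_status: list[np.ndarray]
    seed: int


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooled estimate."""

    q_bar: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float


def fit_imputation_model(
    records: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    ridge: float = 0.16,
) -> ImputationModel:
    """Multinomial-logistic fit of follow-up status on the covariates.

    Fitted on measured children only; every one of the four outcome
    categories must be observed at least once.  ``ridge`` is the
    Gaussian-prior precision on slope coefficients (0 for the plain
    MLE, which fails under quasi-separation).
    """
    measured = records[records["measured"].astype(bool)]
    if measured.empty:
        raise ValueError("no measured children to fit the imputation model on")
    observed = set(measured["status_follow"])
    empty = [c for c in _OUTCOME_ORDER if c not in observed]
    if empty:
        raise EmptyCategoryError(
            f"no measured children in categor{'y' if len(empty) == 1 else 'ies'} "
            f"{empty}; collapse categories or enlarge the sample"
        )

    code = {c: i for i, c in enumerate(_OUTCOME_ORDER)}
    y = measured["status_follow"].map(code).to_numpy()
    X = _design(measured, predictors)
    penalize = np.asarray([0.0 if c == "const" else 1.0 for c in X.columns])
    params, cov, converged = penalized_multinomial(
        X.to_numpy(), y, len(_OUTCOME_ORDER), ridge, penalize
    )
    if not converged or np.abs(params).max() > 1e3:
        raise SeparationError(
            "multinomial fit did not converge; a predictor level is likely "
            "separated from an outcome category (try a larger ridge)"
        )
    return ImputationModel(
        params=params,
        covariance=cov,
        exog_names=tuple(X.columns),
        categories=_OUTCOME_ORDER,
        predictors=tuple(predictors),
        converged=converged,
    )


def _category_probs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Softmax probabilities, baseline category has linear predictor 0."""
    eta = np.column_stack([np.zeros(len(X)), X @ beta])
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def draw_imputations(
    model: ImputationModel,
    records: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """Proper imputation: ``m`` completed status vectors for all children.

    Per imputation a coefficient draw beta* ~ MVN(beta_hat, V_hat) feeds
    the category probabilities at which the missing statuses are
    sampled; observed statuses are copied through unchanged.
    """
    if m < 2:
        raise ValueError("m must be >= 2 for Rubin pooling")
    if not model.converged:
        raise SeparationError("cannot impute from a non-converged model")
    p, km1 = model.params.shape
    cov = model.covariance
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "imputation-model covariance is not positive definite; consider "
            "ridge-regularizing the fit or collapsing sparse categories"
        ) from exc

    measured = records["measured"].astype(bool).to_numpy()
    base = records["status_follow"].to_numpy(dtype=object).copy()
    miss_idx = np.flatnonzero(~measured)
    X_miss = _design(records.loc[~measured], model.predictors)[list(model.exog_names)].to_numpy()

    rng = np.random.default_rng(seed)
    flat_hat = model.params.flatten(order="F")  # matches cov_params ordering
    completed = []
    for _ in range(m):
        beta_star = (flat_hat + chol @ rng.standard_normal(len(flat_hat))).reshape(
            (p, km1), order="F"
        )
        probs = _category_probs(X_miss, beta_star)
        u = rng.random((len(miss_idx), 1))
        draws = (probs.cumsum(axis=1) < u).sum(axis=1)
        filled = base.copy()
        filled[miss_idx] = np.take(np.asarray(model.categories, dtype=object), draws)
        completed.append(filled)
    return ImputationResult(m=m, completed_status=completed, seed=seed)


def rubin_pool(
    estimates: Sequence[float], variances: Sequence[float], conf_level: float = 0.95
) -> PooledEstimate:
    """Pool ``m`` per-imputation estimates by Rubin's rules.

    q_bar = mean(q_t); W = mean(U_t); B = var(q_t, ddof=1);
    T = W + (1 + 1/m) B; df = (m-1)(1 + W / ((1+1/m)B))^2.  With B = 0
    the df are infinite and the normal quantile is used.  The CI is
    clamped to [0, 1] (the estimands here are proportions).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    if len(u) != m:
        raise ValueError("estimates and variances must have equal length")
    q_bar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    if np.ptp(q) <= 1e-12 * max(1.0, abs(q_bar)):
        B = 0.0  # identical estimates up to float noise
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        tq = float(stats.t.ppf(0.5 + conf_level / 2, df))
    else:
        df = float("inf")
        tq = float(stats.norm.ppf(0.5 + conf_level / 2))
    half = tq * np.sqrt(T)
    return PooledEstimate(
        q_bar=q_bar,
        within_var=W,
        between_var=B,
        total_var=T,
        df=df,
        ci_low=float(np.clip(q_bar - half, 0.0, 1.0)),
        ci_high=float(np.clip(q_bar + half, 0.0, 1.0)),
    )


def mi_prevalence(
    records: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    categories: Sequence[str] = OLDER_LABELS,
) -> pd.DataFrame:
    """Pooled MI prevalence table (method tag ``mi``).

    Fits the imputation model, draws ``m`` completed cohorts, estimates
    each category's prevalence on every completed cohort, and pools with
    Rubin's rules.
    """
    model = fit_imputation_model(records, predictors)
    result = draw_imputations(model, records, m=m, seed=seed)
    per_imp = [
        weighted_prevalence(status, categories=categories, method="mi")
        for status in result.completed_status
    ]
    rows = []
    for cat in categories:
        ests = [float(t.set_index("category").loc[cat, "estimate"]) for t in per_imp]
        vars_ = [float(t.set_index("category").loc[cat, "variance"]) for t in per_imp]
        pooled = rubin_pool(ests, vars_)
        rows.append(
            {
                "method": "mi",
                "category": cat,
                "estimate": pooled.q_bar,
                "variance": pooled.total_var,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "n_effective": float(len(records)),
            }
        )
    return pd.DataFrame(rows)
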