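"""Synthetic EHR cohort generator.

Emulates a regional pediatric cohort in which each child carries four
fully observed covariates (sex, rural/urban residence, ordinal household
income, baseline weight status at ages 2-5) and a follow-up BMI z-score
that may be missing.  The generator is the ground truth for every
downstream test: its defaults reproduce the motivating cohort's
covariate marginals (n = 10,811), the baseline z-score is drawn so that
category frequencies match the published baseline distribution exactly
in expectation, the follow-up z-score is correlated with baseline, and
missingness follows a logistic model whose log odds ratios and marginal
measured rate are configurable.

Missingness depends only on the four observed covariates by default, so
the mechanism is MAR given covariates and both IPW and MI are consistent
for the full-cohort prevalence.  Adding a log-OR on the *unobserved*
follow-up status (keys ``follow_*``) produces an MNAR mechanism for
negative-control experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import expit, ndtr, ndtri

from .growth_status import OLDER_LABELS, YOUNG_LABELS, Z_CUTOFFS, classify
from .reference_tables import COHORT_N, MARGINAL_COUNTS, adjusted_log_ors, marginal_measured_rate

__all__ = [
    "CohortConfig",
    "ConfigError",
    "CalibrationError",
    "generate_cohort",
    "apply_missingness",
    "simulate_cohort",
    "mask_unmeasured",
    "indicator_matrix",
    "INDICATOR_NAMES",
    "followup_transition_matrix",
    "true_followup_probs",
    "calibrated_config",
]

#: z interval truncation for baseline draws — keeps every generated
#: record inside the plausibility filter (|z| < 5)
_Z_TRUNC = 4.99

#: half-open z intervals of the four categories on the baseline scale
_CATEGORY_INTERVALS = (
    (-_Z_TRUNC, Z_CUTOFFS[0]),
    (Z_CUTOFFS[0], Z_CUTOFFS[1]),
    (Z_CUTOFFS[1], Z_CUTOFFS[2]),
    (Z_CUTOFFS[2], _Z_TRUNC),
)


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class CalibrationError(RuntimeError):
    """The missingness intercept cannot be calibrated to the target rate."""


def _covariate_indicators(df: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "sex_girl": df["sex"].eq("girl"),
        "res_urban": df["residence"].eq("urban"),
        "income_basic": df["income"].eq(1),
        "income_mid": df["income"].eq(3),
        "income_high": df["income"].eq(4),
        "base_underweight": df["status_base"].eq("underweight"),
        "base_at_risk": df["status_base"].eq("at_risk"),
        "base_overweight_obese": df["status_base"].eq("overweight_obese"),
    }


def _follow_indicators(df: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "follow_underweight": df["status_follow"].eq("underweight"),
        "follow_overweight": df["status_follow"].eq("overweight"),
        "follow_obese": df["status_follow"].eq("obese"),
    }


#: indicator (dummy) names of the observed covariates, reference levels
#: boy / rural / income "<18k" / normal weight
INDICATOR_NAMES = tuple(
    _covariate_indicators(
        pd.DataFrame(
            {"sex": ["boy"], "residence": ["rural"], "income": [2], "status_base": ["normal"]}
        )
    )
)

_FOLLOW_INDICATOR_NAMES = ("follow_underweight", "follow_overweight", "follow_obese")


def indicator_matrix(df: pd.DataFrame, names=INDICATOR_NAMES) -> pd.DataFrame:
    """0/1 design columns for the requested indicator names."""
    available = _covariate_indicators(df)
    if "status_follow" in df.columns:
        available.update(_follow_indicators(df))
    cols = {}
    for name in names:
        if name not in available:
            raise KeyError(f"unknown indicator {name!r}")
        cols[name] = available[name].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _default_income_probs() -> tuple[float, ...]:
    counts = MARGINAL_COUNTS["income"]
    total = sum(counts.values())  # printed counts sum to 10,810
    return tuple(counts[k] / total for k in (1, 2, 3, 4))


def _default_status_probs() -> tuple[float, ...]:
    counts = MARGINAL_COUNTS["status_base"]
    return tuple(counts[k] / COHORT_N for k in YOUNG_LABELS)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the motivating cohort's covariate marginals and
    the 6-9-year follow-up window (measured rate 95.1%, published
    adjusted odds ratios of being measured).  ``z_correlation`` is the
    baseline-to-follow-up z-score correlation; it is a free simulation
    parameter (the source study does not report one) defaulting to 0.6.
    """

    n_children: int = COHORT_N
    p_girl: float = MARGINAL_COUNTS["sex"]["girl"] / COHORT_N
    p_urban: float = MARGINAL_COUNTS["residence"]["urban"] / COHORT_N
    income_probs: tuple[float, ...] = field(default_factory=_default_income_probs)
    baseline_status_probs: tuple[float, ...] = field(default_factory=_default_status_probs)
    z_correlation: float = 0.6
    missingness_log_ors: Mapping[str, float] = field(
        default_factory=lambda: adjusted_log_ors("6-9")
    )
    target_measured_rate: float = marginal_measured_rate("6-9")
    age_window: tuple[int, int] = (6, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ConfigError("n_children must be positive")
        for name, p in (("p_girl", self.p_girl), ("p_urban", self.p_urban)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        for name, probs, k in (
            ("income_probs", self.income_probs, 4),
            ("baseline_status_probs", self.baseline_status_probs, 4),
        ):
            probs = tuple(probs)
            if len(probs) != k or any(p < 0 for p in probs):
                raise ConfigError(f"{name} must be {k} non-negative probabilities")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ConfigError(f"{name} must sum to 1 (got {sum(probs)!r})")
        if not -1.0 <= self.z_correlation <= 1.0:
            raise ConfigError("z_correlation must lie in [-1, 1]")
        if not 0.0 <= self.target_measured_rate <= 1.0:
            raise ConfigError("target_measured_rate must be a probability")
        valid = set(INDICATOR_NAMES) | set(_FOLLOW_INDICATOR_NAMES)
        unknown = set(self.missingness_log_ors) - valid
        if unknown:
            raise ConfigError(f"unknown missingness_log_ors keys: {sorted(unknown)}")
        lo, hi = self.age_window
        if not lo <= hi:
            raise ConfigError("age_window must be (low, high) with low <= high")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)


def calibrated_config(window: str = "6-9", **overrides) -> CohortConfig:
    """A config whose missingness matches the published window ('6-9' or '10-14')."""
    base = CohortConfig(
        missingness_log_ors=adjusted_log_ors(window),
        target_measured_rate=marginal_measured_rate(window),
        age_window=(6, 9) if window == "6-9" else (10, 14),
    )
    return base.replace(**overrides) if overrides else base


def _truncnorm_in_interval(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Map uniforms to truncated-standard-normal draws on [lo, hi)."""
    a, b = ndtr(lo), ndtr(hi)
    return ndtri(a + u * (b - a))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a full latent cohort (follow-up z known for every child).

    Covariates are independent draws from the configured marginals; the
    baseline z is drawn by first choosing the category and then a
    truncated-standard-normal z inside that category's interval, so the
    baseline category frequencies match ``baseline_status_probs`` in
    expectation and every record is internally consistent.  The
    follow-up z is ``rho*z_base + sqrt(1-rho^2)*eps``.  Deterministic
    given ``config.seed``.
    """
    n = config.n_children
    rng = np.random.default_rng(config.seed)

    sex = np.where(rng.random(n) < config.p_girl, "girl", "boy")
    residence = np.where(rng.random(n) < config.p_urban, "urban", "rural")
    income = rng.choice(np.arange(1, 5), size=n, p=np.asarray(config.income_probs))
    cat = rng.choice(4, size=n, p=np.asarray(config.baseline_status_probs))

    intervals = np.asarray(_CATEGORY_INTERVALS)
    z_base = _truncnorm_in_interval(rng.random(n), intervals[cat, 0], intervals[cat, 1])

    rho = config.z_correlation
    z_follow = rho * z_base + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)

    lo, hi = config.age_window
    age_years = rng.integers(lo, hi + 1, size=n)

    df = pd.DataFrame(
        {
            "child_id": [f"c{i:07d}" for i in range(n)],
            "sex": sex,
            "residence": residence,
            "income": income.astype(int),
            "z_base": z_base,
            "status_base": np.take(np.asarray(YOUNG_LABELS, dtype=object), cat),
            "age_years": age_years.astype(int),
            "z_follow": z_follow,
        }
    )
    df["status_follow"] = classify(df["z_follow"].to_numpy(), scheme="older")
    return df


def _linear_predictor(df: pd.DataFrame, log_ors: Mapping[str, float]) -> np.ndarray:
    if not log_ors:
        return np.zeros(len(df))
    X = indicator_matrix(df, names=tuple(log_ors))
    return X.to_numpy() @ np.asarray([log_ors[k] for k in X.columns])


def apply_missingness(
    cohort: pd.DataFrame,
    log_ors: Mapping[str, float],
    target_measured_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Add a Bernoulli ``measured`` flag with a calibrated logistic model.

    ``P(measured) = expit(b0 + sum(log_or * indicator))`` with the
    intercept ``b0`` found by root-finding so the cohort-mean probability
    equals ``target_measured_rate`` (within 1e-6).  Rates of exactly 0
    or 1 are only feasible when every log-OR is zero.
    """
    lp = _linear_predictor(cohort, log_ors)
    any_effect = bool(log_ors) and any(v != 0.0 for v in log_ors.values())
    if target_measured_rate in (0.0, 1.0):
        if any_effect:
            raise CalibrationError(
                "target measured rate of 0 or 1 is unreachable with non-zero log odds ratios"
            )
        out = cohort.copy()
        out["measured"] = bool(target_measured_rate)
        return out

    def gap(b0: float) -> float:
        return float(expit(b0 + lp).mean() - target_measured_rate)

    lo, hi = -20.0, 20.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError("intercept outside [-20, 20]; target rate too extreme")
    b0 = optimize.brentq(gap, lo, hi, xtol=1e-9)
    p = expit(b0 + lp)
    if abs(p.mean() - target_measured_rate) > 1e-6:
        raise CalibrationError("intercept calibration did not reach 1e-6 accuracy")

    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["measured"] = rng.random(len(cohort)) < p
    return out


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort and its measured flags from one config/seed.

    The missingness draw uses a child seed of ``config.seed`` so the
    full simulation is reproducible from the single seed.
    """
    cohort = generate_cohort(config)
    mseed = np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31)
    return apply_missingness(
        cohort, config.missingness_log_ors, config.target_measured_rate, int(mseed)
    )


def mask_unmeasured(cohort: pd.DataFrame) -> pd.DataFrame:
    """Analysis view: blank follow-up values for unmeasured children.

    This is the frame an analyst would actually see; the latent values
    remain available in the generator output for oracle comparisons.
    """
    out = cohort.copy()
    unmeasured = ~out["measured"].astype(bool)
    out.loc[unmeasured, "z_follow"] = np.nan
    out.loc[unmeasured, "status_follow"] = pd.NA
    return out


def followup_transition_matrix(z_correlation: float) -> np.ndarray:
    """Exact P(follow-up category j | baseline category k), 4x4.

    Row k integrates the conditional normal of the follow-up z over the
    truncated-normal baseline density of category k.  Used as the
    analytic oracle for simulation tests (the small probability mass
    beyond |z| = 5 on the follow-up scale is counted in the outer
    categories; the plausibility filter removes it at a rate far below
    Monte-Carlo resolution).
    """
    rho = z_correlation
    s = np.sqrt(max(0.0, 1.0 - rho * rho))
    edges = (-np.inf, *Z_CUTOFFS, np.inf)
    T = np.zeros((4, 4))
    for k, (lo, hi) in enumerate(_CATEGORY_INTERVALS):
        mass = ndtr(hi) - ndtr(lo)
        for j in range(4):
            c_lo, c_hi = edges[j], edges[j + 1]
            if s == 0.0:
                # degenerate: follow-up z is exactly rho * z_base
                def cond(z, a=c_lo, b=c_hi):
                    return float(a < rho * z <= b) if rho != 0 else float(a < 0 <= b)

                val, _ = integrate.quad(lambda z: stats.norm.pdf(z) * cond(z), lo, hi)
            else:
                val, _ = integrate.quad(
                    lambda z: stats.norm.pdf(z)
                    * (ndtr((c_hi - rho * z) / s) - ndtr((c_lo - rho * z) / s)),
                    lo,
                    hi,
                )
            T[k, j] = val / mass
    return T


def true_followup_probs(config: CohortConfig) -> np.ndarray:
    """Generator-truth follow-up category probabilities (length 4).

    The analytic full-cohort prevalence vector that IPW and MI estimate
    under MAR missingness; order follows ``OLDER_LABELS``.
    """
    T = followup_transition_matrix(config.z_correlation)
    p_base = np.asarray(config.baseline_status_probs)
    return p_base @ T


#: follow-up category order of :func:`true_followup_probs`
TRUE_PROB_LABELS = OLDER_LABELS
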