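"""Published reference numbers from the motivating regional EHR cohort study.

These tables carry the printed marginal counts, measurement-coverage
counts and adjusted odds ratios of the cohort of 10,811 children (born
2002-2003, followed in a single primary-care EHR) that this package's
synthetic generator emulates.  They are calibration inputs: the
individual-level data are not public, so the generator reproduces the
covariate marginals and the missingness odds ratios rather than the raw
records.

Notes on the printed tables:

* The income counts sum to 10,810 (one child short of the cohort total;
  every other covariate sums to 10,811), so income probabilities are
  normalized by 10,810.
* Coverage counts are per age at the census date, for a one-year and a
  four-year measurement window; ages with a scheduled well-child visit
  are flagged.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "COHORT_N",
    "COVERAGE_COUNTS",
    "SCHEDULED_AGES",
    "MEASURED_COUNTS",
    "MARGINAL_COUNTS",
    "ADJUSTED_ORS",
    "MEASURED_NOT_MEASURED_BY_SEX",
]

COHORT_N = 10_811

#: ages with a scheduled well-child visit (weight/height routinely taken)
SCHEDULED_AGES = frozenset({0, 1, 2, 3, 4, 6, 8, 11, 14})

#: per-age population and children with >=1 weight+height measurement in a
#: one-year (2016) and a four-year (2013-2016) window
COVERAGE_COUNTS = pd.DataFrame(
    [
        (0, 5570, 5387, 5387),
        (1, 5953, 5780, 5839),
        (2, 5940, 5624, 5898),
        (3, 5874, 4996, 5836),
        (4, 6411, 4992, 6307),
        (5, 6541, 1231, 6342),
        (6, 6564, 5119, 6332),
        (7, 6593, 1323, 6239),
        (8, 6822, 4999, 6415),
        (9, 6605, 1728, 6125),
        (10, 6717, 1923, 5979),
        (11, 6397, 3719, 5808),
        (12, 6518, 1978, 5684),
        (13, 6588, 1147, 5629),
        (14, 6228, 3628, 5243),
    ],
    columns=["age_years", "n_total", "n_measured_1y", "n_measured_4y"],
)

#: (n_measured, n_total) for the two follow-up windows of the cohort
MEASURED_COUNTS = {"6-9": (10_278, COHORT_N), "10-14": (9_610, COHORT_N)}

#: covariate marginals of the cohort (counts)
MARGINAL_COUNTS = {
    "sex": {"boy": 5498, "girl": 5313},
    "residence": {"rural": 6447, "urban": 4364},
    # ordinal income 1..4: basic / <18k / 18-<100k / >=100k euros per year
    "income": {1: 510, 2: 4657, 3: 5546, 4: 97},
    "status_base": {
        "underweight": 78,
        "normal": 7628,
        "at_risk": 2291,
        "overweight_obese": 814,
    },
}

#: measured / not-measured counts by sex in the 6-9 window (the basis of
#: the sex-only 2x2 odds-ratio check)
MEASURED_NOT_MEASURED_BY_SEX = {
    "6-9": {"boy": (5203, 295), "girl": (5075, 238)},
    "10-14": {"boy": (4849, 649), "girl": (4761, 552)},
}

#: adjusted odds ratios of being measured, by follow-up window, keyed by
#: the generator's indicator names (reference levels: boy, normal weight,
#: income <18k, rural -> implicit OR 1)
ADJUSTED_ORS = {
    "6-9": {
        "sex_girl": 1.18,
        "base_underweight": 0.52,
        "base_at_risk": 1.29,
        "base_overweight_obese": 0.99,
        "income_basic": 0.40,
        "income_mid": 1.70,
        "income_high": 1.45,
        "res_urban": 0.79,
    },
    "10-14": {
        "sex_girl": 1.15,
        "base_underweight": 0.53,
        "base_at_risk": 1.14,
        "base_overweight_obese": 1.13,
        "income_basic": 0.57,
        "income_mid": 1.38,
        "income_high": 0.66,
        "res_urban": 0.99,
    },
}


def adjusted_log_ors(window: str) -> dict[str, float]:
    """Log odds ratios of the chosen follow-up window ('6-9' or '10-14')."""
    return {k: math.log(v) for k, v in ADJUSTED_ORS[window].items()}


def marginal_measured_rate(window: str) -> float:
    """Fraction of the cohort measured in the chosen window."""
    n_meas, n_tot = MEASURED_COUNTS[window]
    return n_meas / n_tot
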