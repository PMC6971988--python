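import io
import math

import numpy as np
import pandas as pd
import pytest

from pediprev.growth_status import classify
from pediprev.missingness_ipw import fit_missingness
from pediprev.pipeline import write_cohort
from pediprev.synthetic_cohort import (
    CalibrationError,
    CohortConfig,
    ConfigError,
    apply_missingness,
    calibrated_config,
    generate_cohort,
    mask_unmeasured,
    simulate_cohort,
    true_followup_probs,
)

BIG = CohortConfig(n_children=100_000, seed=11)


@pytest.fixture(scope="module")
def big_cohort() -> pd.DataFrame:
    return generate_cohort(BIG)


class TestGenerateCohort:
    def test_record_count_and_schema(self, big_cohort):
        assert len(big_cohort) == BIG.n_children
        assert big_cohort["child_id"].is_unique

    def test_covariate_marginals_match_config(self, big_cohort):
        n = len(big_cohort)
        for observed, p in [
            ((big_cohort.sex == "girl").mean(), BIG.p_girl),
            ((big_cohort.residence == "urban").mean(), BIG.p_urban),
        ]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 3 * se

    def test_baseline_status_frequencies_converge(self, big_cohort):
        n = len(big_cohort)
        freqs = big_cohort.status_base.value_counts(normalize=True)
        for label, p in zip(
            ("underweight", "normal", "at_risk", "overweight_obese"), BIG.baseline_status_probs
        ):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freqs.get(label, 0.0) - p) < 3 * se

    def test_status_consistent_with_z_and_plausible(self, big_cohort):
        relabelled = classify(big_cohort.z_base.to_numpy(), scheme="young")
        assert (relabelled == big_cohort.status_base.to_numpy()).all()
        assert big_cohort.z_base.abs().max() < 5

    def test_degenerate_full_correlation(self):
        cfg = CohortConfig(n_children=2000, z_correlation=1.0, seed=3)
        cohort = generate_cohort(cfg)
        assert np.allclose(cohort.z_follow, cohort.z_base)
        same_band = classify(cohort.z_base.to_numpy(), "older") == cohort.status_follow.to_numpy()
        assert same_band.all()

    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_children=500, seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        for frame, buf in ((a, buf_a), (b, buf_b)):
            frame = frame.assign(measured=True)
            write_cohort(frame, buf)
        assert buf_a.getvalue() == buf_b.getvalue()

    @pytest.mark.parametrize(
        "bad",
        [
            {"income_probs": (0.5, 0.5, 0.1, 0.0)},
            {"baseline_status_probs": (0.2, 0.2, 0.2, 0.2)},
            {"p_girl": 1.2},
            {"z_correlation": 1.5},
            {"missingness_log_ors": {"not_a_covariate": 0.1}},
            {"n_children": 0},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            CohortConfig(**bad)


class TestApplyMissingness:
    def test_intercept_only_rate(self, big_cohort):
        out = apply_missingness(big_cohort, {}, 0.951, seed=5)
        se = math.sqrt(0.951 * 0.049 / len(out))
        assert abs(out.measured.mean() - 0.951) < 3 * se

    def test_calibrated_rate_with_effects(self, big_cohort):
        cfg = calibrated_config("6-9")
        out = apply_missingness(big_cohort, cfg.missingness_log_ors, 0.951, seed=5)
        # the calibrated *probabilities* average to the target within 1e-6;
        # the realized rate fluctuates binomially around it
        se = math.sqrt(0.951 * 0.049 / len(out))
        assert abs(out.measured.mean() - 0.951) < 3 * se

    def test_target_one_all_measured(self, big_cohort):
        out = apply_missingness(big_cohort, {}, 1.0, seed=5)
        assert out.measured.all()

    def test_infeasible_target_with_effects(self, big_cohort):
        with pytest.raises(CalibrationError):
            apply_missingness(big_cohort, {"sex_girl": 0.5}, 1.0, seed=5)

    def test_mnar_key_hits_unobserved_status(self):
        cfg = CohortConfig(
            n_children=50_000, baseline_status_probs=(0.02, 0.55, 0.25, 0.18), z_correlation=0.8
        )
        cohort = generate_cohort(cfg)
        out = apply_missingness(cohort, {"follow_obese": math.log(0.2)}, 0.8, seed=9)
        obese = out.status_follow == "obese"
        assert out.loc[obese, "measured"].mean() < out.loc[~obese, "measured"].mean() - 0.05


class TestParameterRecovery:
    def test_single_log_or_recovered(self):
        cfg = CohortConfig(n_children=20_000, seed=21)
        cohort = generate_cohort(cfg)
        truth = math.log(0.40)
        out = apply_missingness(cohort, {"income_basic": truth}, 0.951, seed=22)
        fit = fit_missingness(out)
        b = float(fit.coefficients["income_basic"])
        se = math.sqrt(float(fit.covariance.loc["income_basic", "income_basic"]))
        # 99.9% band: a fixed-seed draw should essentially never miss it
        assert abs(b - truth) < 3.3 * se

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n in (5_000, 20_000):
            cfg = CohortConfig(n_children=n, seed=31)
            out = apply_missingness(
                generate_cohort(cfg), {"income_mid": math.log(1.70)}, 0.90, seed=32
            )
            fit = fit_missingness(out)
            lo, hi = fit.or_ci("income_mid")
            widths[n] = math.log(hi) - math.log(lo)
        # log-scale CI width ~ 1/sqrt(n): quadrupling n halves the width
        assert widths[5_000] / widths[20_000] == pytest.approx(2.0, rel=0.35)


class TestTruthOracle:
    def test_analytic_follow_probs_match_monte_carlo(self):
        cfg = CohortConfig(n_children=200_000, z_correlation=0.6, seed=8)
        cohort = generate_cohort(cfg)
        truth = true_followup_probs(cfg)
        assert truth.sum() == pytest.approx(1.0, abs=1e-9)
        freqs = cohort.status_follow.value_counts(normalize=True)
        for label, p in zip(("underweight", "normal", "overweight", "obese"), truth):
            se = math.sqrt(p * (1 - p) / len(cohort))
            assert abs(freqs.get(label, 0.0) - p) < 3.5 * se


class TestMasking:
    def test_followup_blanked_iff_unmeasured(self):
        cohort = simulate_cohort(CohortConfig(n_children=3000, seed=4))
        masked = mask_unmeasured(cohort)
        um = ~masked.measured
        assert masked.loc[um, "z_follow"].isna().all()
        assert masked.loc[um, "status_follow"].isna().all()
        pd.testing.assert_series_equal(
            masked.loc[~um, "z_follow"], cohort.loc[~um, "z_follow"]
        )
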