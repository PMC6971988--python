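import math
import warnings

import numpy as np
import pandas as pd
import pytest

from pediprev.imputation import (
    EmptyCategoryError,
    draw_imputations,
    fit_imputation_model,
    mi_prevalence,
    rubin_pool,
)
from pediprev.missingness_ipw import _design
from pediprev.synthetic_cohort import (
    CohortConfig,
    apply_missingness,
    followup_transition_matrix,
    generate_cohort,
    mask_unmeasured,
    simulate_cohort,
    true_followup_probs,
)

#: dense configuration: every outcome category well populated at every
#: covariate level, so the unpenalized MLE exists
DENSE = CohortConfig(
    n_children=8000, baseline_status_probs=(0.1, 0.4, 0.3, 0.2), z_correlation=0.3, seed=7
)


class TestRubinPool:
    def test_worked_example(self):
        pooled = rubin_pool([0.10, 0.12], [0.001, 0.001])
        assert pooled.q_bar == pytest.approx(0.11)
        assert pooled.within_var == pytest.approx(0.001)
        assert pooled.between_var == pytest.approx(0.0002)
        assert pooled.total_var == pytest.approx(0.0013)
        m, W, B = 2, 0.001, 0.0002
        assert pooled.df == pytest.approx((m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2)

    def test_identical_estimates_collapse_to_single_imputation(self):
        pooled = rubin_pool([0.2, 0.2, 0.2], [0.004, 0.004, 0.004])
        assert pooled.between_var == 0.0
        assert pooled.total_var == pytest.approx(0.004)
        assert pooled.df == math.inf
        half = 1.959964 * math.sqrt(0.004)
        assert pooled.ci_low == pytest.approx(max(0.0, 0.2 - half), abs=1e-6)

    def test_zero_within_variance(self):
        pooled = rubin_pool([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])
        assert pooled.total_var == pytest.approx((1 + 1 / 3) * np.var([0.1, 0.2, 0.3], ddof=1))

    def test_requires_two_imputations(self):
        with pytest.raises(ValueError):
            rubin_pool([0.1], [0.001])


class TestFitImputationModel:
    def test_intercept_only_reproduces_frequencies(self):
        cohort = simulate_cohort(DENSE)
        model = fit_imputation_model(cohort, predictors=())
        probs = _softmax_probs(model, n=1)
        measured = cohort[cohort.measured]
        freqs = measured.status_follow.value_counts(normalize=True)
        for cat, p in zip(model.categories, probs[0]):
            assert p == pytest.approx(freqs[cat], abs=1e-8)

    def test_matches_statsmodels_mle_on_dense_data(self):
        import statsmodels.api as sm

        cohort = simulate_cohort(DENSE)
        model = fit_imputation_model(cohort, ridge=0.0)
        measured = cohort[cohort.measured]
        code = {c: i for i, c in enumerate(model.categories)}
        X = _design(measured, model.predictors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(measured.status_follow.map(code).to_numpy(), X).fit(
                disp=0, maxiter=200
            )
        assert np.abs(model.params - np.asarray(res.params)).max() < 1e-6
        assert np.abs(model.covariance - np.asarray(res.cov_params())).max() < 1e-8

    def test_conditional_probs_recover_generator_transitions(self):
        cohort = simulate_cohort(DENSE.replace(n_children=50_000, seed=17))
        model = fit_imputation_model(cohort, predictors=("status_base",))
        T = followup_transition_matrix(DENSE.z_correlation)
        # design column order: const, base_underweight, base_at_risk, base_overweight_obese
        base_rows = {
            "normal": [1.0, 0, 0, 0],
            "underweight": [1.0, 1, 0, 0],
            "at_risk": [1.0, 0, 1, 0],
            "overweight_obese": [1.0, 0, 0, 1],
        }
        measured = cohort[cohort.measured]
        for k, base in enumerate(("underweight", "normal", "at_risk", "overweight_obese")):
            x = np.asarray([base_rows[base]])
            probs = _softmax_row(model, x)
            n_k = int((measured.status_base == base).sum())
            order = ("underweight", "normal", "overweight", "obese")
            for j, cat in enumerate(order):
                p = T[k, j]
                se = math.sqrt(max(p * (1 - p), 1e-6) / n_k)
                assert abs(probs[model.categories.index(cat)] - p) < 4 * se

    def test_empty_category_names_the_gap(self):
        cohort = simulate_cohort(DENSE.replace(n_children=300, seed=3))
        cohort.loc[cohort.measured & (cohort.status_follow == "obese"), "measured"] = False
        with pytest.raises(EmptyCategoryError, match="obese"):
            fit_imputation_model(cohort)


def _softmax_probs(model, n):
    X = np.ones((n, len(model.exog_names)))
    return _softmax(X @ model.params)


def _softmax_row(model, x):
    return _softmax(x @ model.params)[0]


def _softmax(eta):
    eta = np.column_stack([np.zeros(len(eta)), eta])
    e = np.exp(eta - eta.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class TestDrawImputations:
    def test_no_missing_values_gives_identical_copies(self):
        cohort = generate_cohort(DENSE.replace(n_children=2000))
        cohort = apply_missingness(cohort, {}, 1.0, seed=1)
        model = fit_imputation_model(cohort)
        result = draw_imputations(model, cohort, m=5, seed=2)
        for status in result.completed_status[1:]:
            assert (status == result.completed_status[0]).all()
        table = mi_prevalence(cohort, m=5, seed=2).set_index("category")
        cc = cohort.status_follow.value_counts(normalize=True)
        assert table.loc["obese", "estimate"] == pytest.approx(cc["obese"])

    def test_observed_statuses_never_altered(self):
        cohort = mask_unmeasured(simulate_cohort(DENSE))
        model = fit_imputation_model(cohort)
        result = draw_imputations(model, cohort, m=3, seed=5)
        measured = cohort.measured.to_numpy()
        observed = cohort.status_follow.to_numpy(dtype=object)
        for status in result.completed_status:
            assert (status[measured] == observed[measured]).all()

    def test_zero_covariance_leaves_only_sampling_noise(self):
        cohort = mask_unmeasured(
            simulate_cohort(DENSE.replace(target_measured_rate=0.6, seed=23))
        )
        model = fit_imputation_model(cohort)
        model.covariance = np.zeros_like(model.covariance)
        result = draw_imputations(model, cohort, m=60, seed=6)
        n = len(cohort)
        n_miss = int((~cohort.measured).sum())
        ests = [float((s == "obese").mean()) for s in result.completed_status]
        # between-imputation SD should be close to pure binomial draw noise
        p_miss = np.mean(ests) * n / n_miss  # rough per-missing obesity rate
        expected_sd = math.sqrt(max(p_miss, 1e-6) * (1 - min(p_miss, 1.0)) * n_miss) / n
        assert np.std(ests, ddof=1) < 3 * expected_sd

    def test_requires_at_least_two(self):
        cohort = mask_unmeasured(simulate_cohort(DENSE))
        model = fit_imputation_model(cohort)
        with pytest.raises(ValueError):
            draw_imputations(model, cohort, m=1, seed=0)


class TestMIPrevalence:
    def test_pooled_estimates_sum_to_one_and_hit_truth(self):
        cfg = DENSE.replace(n_children=20_000, target_measured_rate=0.85, seed=29)
        cohort = mask_unmeasured(simulate_cohort(cfg))
        table = mi_prevalence(cohort, m=10, seed=30).set_index("category")
        assert table["estimate"].sum() == pytest.approx(1.0, abs=1e-9)
        truth = true_followup_probs(cfg)
        for cat, p in zip(("underweight", "normal", "overweight", "obese"), truth):
            se = math.sqrt(table.loc[cat, "variance"])
            assert abs(table.loc[cat, "estimate"] - p) < 3.5 * se

    def test_seed_determinism(self):
        cohort = mask_unmeasured(simulate_cohort(DENSE))
        a = mi_prevalence(cohort, m=4, seed=11)
        b = mi_prevalence(cohort, m=4, seed=11)
        pd.testing.assert_frame_equal(a, b)
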