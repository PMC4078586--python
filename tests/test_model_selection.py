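"""Cross-validation against brute-force oracles; the 21-approach table."""

import warnings

import numpy as np
import pytest

from nephqc import (
    RangeWarning,
    adjust_pm,
    cf_predict,
    comparison_table,
    fit_cf,
    fit_combined_arrays,
    fit_gravimetric,
    loo_cv,
    loo_cv_combined,
    loo_cv_gravimetric,
    predict_combined,
    predict_gravimetric,
    two_step_cv,
)
from nephqc.humidity import ObservedCF
from nephqc.model_selection import approach_specs
from nephqc.presets import published_cf_model
from nephqc.synthetic import (
    GeneratorConfig,
    generate_campaign,
    generate_from_two_step,
)

GRAV_FORMS = ["linear_origin", "loglog", "loglog_spline", "loglog_quadratic"]
COMBINED_FORMS = ["loglinear", "loglinear_spline", "loglinear_quadratic"]


@pytest.fixture(scope="module")
def small_campaign():
    return generate_campaign(GeneratorConfig(seed=21, n_samples=18))


def brute_force_loo_gravimetric(han, grav, form):
    """Independent nested loop: refit every fold from scratch."""
    n = len(han)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        m = fit_gravimetric(han[keep], grav[keep], form)
        preds[i] = predict_gravimetric(m, han[i])
    return np.sqrt(np.mean((preds - grav) ** 2)), preds


def brute_force_loo_combined(samples, form):
    n = len(samples)
    preds = np.empty(n)
    for i in range(n):
        tr = [s for j, s in enumerate(samples) if j != i]
        m = fit_combined_arrays(
            [s.neph_pm for s in tr], [s.grav_pm for s in tr], [s.rh for s in tr], form
        )
        preds[i] = predict_combined(m, samples[i].neph_pm, samples[i].rh)
    obs = np.array([s.grav_pm for s in samples])
    return np.sqrt(np.mean((preds - obs) ** 2)), preds


def brute_force_two_step(samples, cf_form, use_threshold, grav_form, cf_model=None):
    n = len(samples)
    preds = np.empty(n)
    for i in range(n):
        tr = [s for j, s in enumerate(samples) if j != i]
        if cf_model is None:
            m_cf = fit_cf(
                [ObservedCF(s.sample_id, s.rh, s.neph_pm / s.grav_pm) for s in tr],
                cf_form,
            )
        else:
            m_cf = cf_model
        han_tr = np.array(
            [s.neph_pm / cf_predict(m_cf, s.rh, use_threshold) for s in tr]
        )
        m_g = fit_gravimetric(han_tr, np.array([s.grav_pm for s in tr]), grav_form)
        han_i = samples[i].neph_pm / cf_predict(m_cf, samples[i].rh, use_threshold)
        preds[i] = predict_gravimetric(m_g, han_i)
    obs = np.array([s.grav_pm for s in samples])
    return np.sqrt(np.mean((preds - obs) ** 2)), preds


@pytest.mark.filterwarnings("ignore::nephqc.errors.RangeWarning")
class TestLooCVOracle:
    @pytest.mark.parametrize("form", GRAV_FORMS)
    def test_gravimetric_forms_match_brute_force(self, small_campaign, form):
        han = np.array([s.neph_pm for s in small_campaign])
        grav = np.array([s.grav_pm for s in small_campaign])
        res = loo_cv_gravimetric(han, grav, form)
        rmse, preds = brute_force_loo_gravimetric(han, grav, form)
        assert res.rmse == pytest.approx(rmse, rel=1e-10)
        assert np.allclose(res.predictions, preds, rtol=1e-10)

    @pytest.mark.parametrize("form", COMBINED_FORMS)
    def test_combined_forms_match_brute_force(self, small_campaign, form):
        res = loo_cv_combined(small_campaign, form)
        rmse, preds = brute_force_loo_combined(small_campaign, form)
        assert res.rmse == pytest.approx(rmse, rel=1e-10)
        assert np.allclose(res.predictions, preds, rtol=1e-10)

    def test_exact_model_data_gives_zero_rmse(self):
        han = np.exp(np.linspace(6.6, 11.0, 12))
        grav = np.exp(2.5) * han**0.72
        res = loo_cv_gravimetric(han, grav, "loglog")
        assert res.rmse <= 1e-6 * grav.mean()

    def test_fold_count_matches_sample_count(self, small_campaign):
        res = loo_cv_combined(small_campaign, "loglinear")
        assert res.n_folds == len(small_campaign)

    def test_rmse_invariant_under_permutation(self, small_campaign):
        res = loo_cv_combined(small_campaign, "loglinear")
        shuffled = [small_campaign[i] for i in np.random.default_rng(0).permutation(18)]
        res2 = loo_cv_combined(shuffled, "loglinear")
        assert res.rmse == pytest.approx(res2.rmse, rel=1e-12)


@pytest.mark.filterwarnings("ignore::nephqc.errors.RangeWarning")
class TestTwoStepCV:
    def test_matches_brute_force_nested_loop(self):
        samples = generate_campaign(GeneratorConfig(seed=31, n_samples=10))
        res = two_step_cv(samples, "richards_log", False, "loglog")
        rmse, preds = brute_force_two_step(samples, "richards_log", False, "loglog")
        assert res.rmse == pytest.approx(rmse, rel=1e-10)
        assert np.allclose(res.predictions, preds, rtol=1e-10)

    def test_fixed_published_cf_matches_brute_force(self):
        samples = generate_campaign(GeneratorConfig(seed=32, n_samples=10))
        m1a = published_cf_model("1a", with_threshold=True)
        res = two_step_cv(
            samples, "chakrabarti", True, "loglog_quadratic", cf_model=m1a
        )
        rmse, _ = brute_force_two_step(
            samples, "chakrabarti", True, "loglog_quadratic", cf_model=m1a
        )
        assert res.rmse == pytest.approx(rmse, rel=1e-10)

    def test_generative_match_has_zero_error(self, compatible_campaign):
        res = two_step_cv(compatible_campaign, "richards_log", False, "loglog")
        scale = np.mean([s.grav_pm for s in compatible_campaign])
        assert res.rmse <= 1e-6 * scale

    def test_misspecified_cf_form_is_worse(self, compatible_campaign):
        good = two_step_cv(compatible_campaign, "richards_log", False, "loglog")
        bad = two_step_cv(compatible_campaign, "chakrabarti", False, "loglog")
        assert bad.rmse > good.rmse
        assert bad.rmse > 1.0  # clearly nonzero, not just float noise


@pytest.mark.filterwarnings("ignore::nephqc.errors.RangeWarning")
class TestComparisonTable:
    def test_enumerates_21_approaches_18_two_step(self, small_campaign):
        table, results = comparison_table(small_campaign)
        assert len(table) == 21
        assert (table["method"] == "two_step").sum() == 18
        assert (table["method"] == "combined").sum() == 3
        assert list(table["approach"]) == list(range(1, 22))
        assert all(results[k].n_folds == len(small_campaign) for k in results)

    def test_subset_selection(self, small_campaign):
        table, _ = comparison_table(small_campaign, approaches=[1, 6, 21])
        assert list(table["approach"]) == [1, 6, 21]

    def test_approach_numbering_blocks(self):
        specs = {s["approach"]: s for s in approach_specs()}
        assert specs[1]["method"] == "combined"
        # 4-12 without threshold, 13-21 with
        assert all(specs[i]["threshold"] is False for i in range(4, 13))
        assert all(specs[i]["threshold"] is True for i in range(13, 22))
        # humidity cycle 1a,1b,2a within each conversion block
        assert [specs[i]["humidity_eq"] for i in (4, 5, 6)] == ["1a", "1b", "2a"]
        assert [specs[i]["conversion"] for i in (4, 7, 10)] == ["eq4", "eq5", "eq6"]

    def test_in_sample_rmse_never_worse_for_nested_spline(self, small_campaign):
        """Adding a hinge cannot raise the training RMSE (the CV RMSE may
        go either way)."""
        han = np.array([s.neph_pm for s in small_campaign])
        grav = np.array([s.grav_pm for s in small_campaign])
        base = fit_gravimetric(han, grav, "loglog")
        spl = fit_gravimetric(han, grav, "loglog_spline")
        rmse_base = np.sqrt(np.mean((predict_gravimetric(base, han) - grav) ** 2))
        rmse_spl = np.sqrt(np.mean((predict_gravimetric(spl, han) - grav) ** 2))
        assert rmse_spl <= rmse_base + 1e-9


class TestCFScaleRMSE:
    def test_fixed_model_uses_plain_residual_rmse(self):
        from nephqc.model_selection import cf_model_rmse

        m = published_cf_model("1a")
        obs = [ObservedCF("a", 0.8, 2.0), ObservedCF("b", 0.4, 0.9)]
        res = cf_model_rmse(obs, cf_model=m)
        pred = np.array([cf_predict(m, 0.8), cf_predict(m, 0.4)])
        expected = np.sqrt(np.mean((pred - np.array([2.0, 0.9])) ** 2))
        assert res.rmse == pytest.approx(expected, rel=1e-12)

    def test_refit_model_uses_leave_one_out(self):
        from nephqc.model_selection import cf_model_rmse

        rng = np.random.default_rng(3)
        rh = rng.uniform(0.2, 0.9, 12)
        cf = np.exp(-0.7 - 0.8 * np.log1p(-rh) + rng.normal(0, 0.2, 12))
        obs = [ObservedCF(f"s{i}", r, c) for i, (r, c) in enumerate(zip(rh, cf))]
        res = cf_model_rmse(obs, form="richards_log")
        preds = np.empty(12)
        for i in range(12):
            m = fit_cf([o for j, o in enumerate(obs) if j != i], "richards_log")
            preds[i] = cf_predict(m, obs[i].rh)
        assert res.rmse == pytest.approx(np.sqrt(np.mean((preds - cf) ** 2)), rel=1e-10)
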