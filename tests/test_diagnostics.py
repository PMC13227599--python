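"""Residual diagnostics, VIF, cross-validation and bootstrap."""

from helpers import agg_from as _agg_from

import dataclasses

import numpy as np
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from prsopt import (
    DesignSpec,
    aggregate_replicates,
    bootstrap_model,
    breusch_pagan,
    build_design_matrix,
    diagnose,
    durbin_watson,
    fit_quadratic_surface,
    generate_viability_table,
    kfold_cv_rmse,
    shapiro_wilk,
    vif,
)
from prsopt.diagnostics import vif_report
from prsopt.errors import UndefinedStatisticError


class TestDurbinWatson:
    def test_constant_residuals(self):
        assert durbin_watson([2.0] * 10) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [4, 10, 101])
    def test_alternating_closed_form(self, n):
        e = np.tile([1.0, -1.0], n)[:n]
        # sum of (e_t - e_{t-1})^2 = 4(n-1); sum e^2 = n
        assert durbin_watson(e) == pytest.approx(4 * (n - 1) / n)

    def test_iid_normal_near_two(self):
        e = np.random.default_rng(0).standard_normal(1000)
        assert abs(durbin_watson(e) - 2.0) < 0.15

    def test_textbook_formula_agreement(self):
        e = np.random.default_rng(1).standard_normal(50)
        expected = np.sum(np.diff(e) ** 2) / np.sum(e**2)
        assert durbin_watson(e) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            durbin_watson(np.zeros(10))

    def test_bounded_zero_four(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            e = rng.standard_normal(rng.integers(3, 40))
            assert 0.0 <= durbin_watson(e) <= 4.0


class TestBreuschPagan:
    def test_textbook_lm_statistic(self, tumor_fit):
        bp_stat, bp_p = breusch_pagan(tumor_fit)
        # independent reimplementation: n * R^2 of e^2 on the design
        est = tumor_fit.estimator
        D, _ = build_design_matrix(tumor_fit.doses, tumor_fit.design)
        e2 = est.residuals_**2
        beta = np.linalg.lstsq(D, e2, rcond=None)[0]
        resid = e2 - D @ beta
        r2 = 1 - resid @ resid / np.sum((e2 - e2.mean()) ** 2)
        import scipy.stats

        lm = est.n_obs_ * r2
        assert bp_stat == pytest.approx(lm, rel=1e-6)
        assert bp_p == pytest.approx(
            scipy.stats.chi2.sf(lm, D.shape[1] - 1), rel=1e-6
        )

    def test_detects_variance_growing_with_dose(self, panel, spec):
        # heteroscedastic: noise SD proportional to metformin dose
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            X = rng.uniform(0, 1, size=(200, 3)) * [1e-4, 10, 6.5]
            y = 100 - 4 * X[:, 1] + rng.normal(0, 0.3 + 2.0 * X[:, 1] / 10, 200)
            fit = fit_quadratic_surface(_agg_from(X, y, panel), spec)
            if breusch_pagan(fit)[1] < 0.05:
                hits += 1
        assert hits >= 24  # >= 80% power


class TestShapiroWilk:
    def test_matches_scipy_and_detects_skew(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for s in range(30):
            e = np.random.default_rng(s).exponential(size=100)
            if shapiro_wilk(e)[1] < 0.05:
                rejections += 1
        assert rejections >= 27  # >= 90% power against exponential

    def test_range_and_identical_errors(self):
        with pytest.raises(UndefinedStatisticError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            shapiro_wilk(np.ones(20))


class TestVif:
    def test_orthogonal_columns_unity(self):
        D = np.kron(np.eye(3), np.ones(4)).T.reshape(12, 3) - 1 / 3
        # use an explicitly orthogonal pair instead
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        D = np.column_stack([np.sin(t), np.cos(t), np.sin(2 * t)])
        for v in vif(D, ["a", "b", "c"]).values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(500)
        c = rng.standard_normal(500)
        a -= a.mean()
        c -= c.mean() + a * (a @ c) / (a @ a)  # orthogonalize
        c = c - c.mean()
        b = 0.8 * a / a.std() + np.sqrt(1 - 0.64) * c / c.std()
        r = np.corrcoef(a, b)[0, 1]
        vals = vif(np.column_stack([a, b]), ["a", "b"])
        expected = 1.0 / (1.0 - r**2)
        assert vals["a"] == pytest.approx(expected, rel=1e-9)
        assert vals["b"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1 / (1 - 0.64), rel=1e-2)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        vals = vif(np.column_stack([a, a, b]), ["a1", "a2", "b"])
        assert np.isinf(vals["a1"]) and np.isinf(vals["a2"])
        assert np.isfinite(vals["b"])

    def test_matches_statsmodels(self, tumor_fit):
        spec_c = dataclasses.replace(tumor_fit.design, center_for_vif=True)
        D, names = build_design_matrix(tumor_fit.doses, spec_c)
        ours = vif(D[:, 1:], names[1:])
        Dc = np.column_stack([np.ones(len(D)), D[:, 1:]])
        for j, name in enumerate(names[1:], start=1):
            assert ours[name] == pytest.approx(
                variance_inflation_factor(Dc, j), rel=1e-8
            )

    def test_rescaled_centered_beats_raw_powers(self, tumor_fit, panel):
        # conditioning invariant: raw powers of ~1e-4 dilutions inflate VIF
        vals_good, _ = vif_report(tumor_fit)
        spec_raw = DesignSpec(
            agents=panel, internal_rescale=False, center_for_vif=False
        )
        D_raw, names = build_design_matrix(tumor_fit.doses, spec_raw)
        vals_raw = vif(D_raw[:, 1:], names[1:])
        assert max(vals_good.values()) < max(vals_raw.values())
        assert all(np.isfinite(v) for v in vals_good.values())


class TestKFoldCV:
    def test_noise_free_rmse_tiny(self, noiseless_agg, spec):
        assert kfold_cv_rmse(noiseless_agg, spec, k=5, seed=0) <= 1e-6

    def test_estimates_noise_scale(self, truths, panel, spec):
        # direct sigma=5 noise on condition means over a dense grid
        from prsopt.synthetic import default_dose_grid

        surf = truths["tumor"].surface()
        grid = default_dose_grid(panel, n_points=60)
        X = np.array([d.as_array(panel) for d in grid])
        mu = surf.predict(X)
        vals = []
        for s in range(5):
            y = mu + np.random.default_rng(s).normal(0, 5, len(mu))
            vals.append(kfold_cv_rmse(_agg_from(X, y, panel), spec, k=5, seed=s))
        assert np.mean(vals) == pytest.approx(5.0, rel=0.3)

    def test_deterministic_under_seed(self, noisy_agg, spec):
        a = kfold_cv_rmse(noisy_agg, spec, k=5, seed=11)
        b = kfold_cv_rmse(noisy_agg, spec, k=5, seed=11)
        assert a == b
        assert kfold_cv_rmse(noisy_agg, spec, k=5, seed=12) != a

    def test_k_validation(self, noisy_agg, spec):
        with pytest.raises(ValueError):
            kfold_cv_rmse(noisy_agg, spec, k=1)


class TestBootstrap:
    def test_deterministic_under_seed(self, noisy_agg, spec):
        a = bootstrap_model(noisy_agg, spec, B=150, seed=5)
        b = bootstrap_model(noisy_agg, spec, B=150, seed=5)
        assert a["bootstrap_ci"] == b["bootstrap_ci"]

    def test_ci_contains_point_estimate(self, noisy_agg, spec, tumor_fit):
        out = bootstrap_model(noisy_agg, spec, B=200, seed=0)
        for term, (lo, hi) in out["bootstrap_ci"].items():
            assert lo <= tumor_fit.coefficients[term] <= hi

    def test_zero_noise_ci_width_zero(self, noiseless_agg, spec):
        out = bootstrap_model(noiseless_agg, spec, B=120, seed=0)
        for term, (lo, hi) in out["bootstrap_ci"].items():
            assert hi - lo <= 1e-6 * max(1.0, abs(hi))

    def test_coverage_of_true_intercept(self, truths, spec):
        # 95% percentile CI should cover the true intercept ~95% of the time
        truth = truths["tumor"]
        covered = 0
        n_outer = 40
        for s in range(n_outer):
            t = dataclasses.replace(truth, noise_sd=4.0, bio_rep_sd=0.0, seed=1000 + s)
            agg = aggregate_replicates(generate_viability_table(t))
            lo, hi = bootstrap_model(agg, spec, B=150, seed=s)["bootstrap_ci"][
                "intercept"
            ]
            if lo <= truth.coefficients["intercept"] <= hi:
                covered += 1
        assert covered >= 30  # pr(X<30 | p=0.95) is negligible

    def test_b_validation(self, noisy_agg, spec):
        with pytest.raises(ValueError):
            bootstrap_model(noisy_agg, spec, B=50)


def test_full_report_assembly(tumor_fit, noisy_agg):
    report = diagnose(tumor_fit, noisy_agg, k=5, B=120, seed=3)
    assert 0 < report.shapiro_w <= 1 and 0 <= report.shapiro_p <= 1
    assert report.bp_stat >= 0 and 0 <= report.bp_p <= 1
    assert 0 <= report.dw_stat <= 4
    assert set(report.vif) == set(tumor_fit.design.term_names[1:])
    assert report.cv_rmse >= 0 and report.cv_k == 5
    assert set(report.bootstrap_ci) == set(tumor_fit.design.term_names)
    d = report.to_dict()
    assert d["bootstrap_B"] == 120 and d["seed"] == 3
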