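"""Objective function, multi-start fitting, and the parameter-fixing estimators."""

import numpy as np
import pytest

import radpop as rp
from radpop.fitting import TA_BY_DOSE, _safe_sd


def _course(dose, C0, times, mean, sd=None, idx=1):
    sd = np.full_like(mean, 1.0) if sd is None else sd
    return rp.TimeCourse(dose, idx, C0, times, mean, sd)


class TestChi2Reduced:
    def _exact_curve(self, dose=10.0):
        p = rp.ModelParams(dose=dose, Ta=18.0, lambda_u=0.12, lambda_r=1e-3, lambda_s=0.03)
        t = np.arange(0.0, 144.001, 1.5)
        obs = rp.simulate(p, 1e-4, t).observed
        return p, _course(dose, 1e-4, t, obs, np.full_like(obs, 1e-5))

    def test_zero_at_exact_model(self):
        p, data = self._exact_curve()
        assert rp.chi2_reduced(data, p) == pytest.approx(0.0, abs=1e-10)

    def test_unit_residuals_give_n_over_ndof(self):
        # n=4 points, k=1 free parameter, each residual = sigma -> 4/3
        p = rp.ModelParams(dose=0.0, Ta=0.0, lambda_u=0.0, lambda_r=0.105)
        t = np.array([0.0, 1.5, 3.0, 4.5])
        model = rp.simulate(p, 1e-4, t, logistic=True).observed
        sd = np.full(4, 3e-6)
        data = _course(0.0, 1e-4, t, model + sd, sd)
        assert rp.chi2_reduced(data, p, free_names=("lambda_r",)) == pytest.approx(4 / 3)

    def test_doubling_sigma_quarters_objective(self):
        p, data = self._exact_curve()
        noisy = _course(
            data.dose, data.C0, data.times, data.mean_density * 1.1, data.sd_density
        )
        wide = _course(
            data.dose, data.C0, data.times, data.mean_density * 1.1, 2 * data.sd_density
        )
        assert rp.chi2_reduced(wide, p) == pytest.approx(rp.chi2_reduced(noisy, p) / 4)

    def test_points_above_confluence_threshold_ignored(self):
        p, data = self._exact_curve()
        spiked = data.mean_density.copy()
        spiked[-3:] = 5e-3  # way above CT=1.3e-3
        perturbed = _course(data.dose, data.C0, data.times, spiked, data.sd_density)
        base = rp.chi2_reduced(data, p)
        assert rp.chi2_reduced(perturbed, p) == pytest.approx(
            np.sum(((data.mean_density - rp.simulate(p, 1e-4, data.times).observed)
                    / data.sd_density)[:-3] ** 2)
            / (len(data.times) - 3 - 3)
        )
        assert base == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        p = rp.ModelParams(dose=0.0, Ta=0.0, lambda_u=0.0, lambda_r=0.105)
        t = np.array([0.0, 1.5, 3.0])
        data = _course(0.0, 1e-4, t, np.full(3, 1e-4))
        with pytest.raises(ValueError):
            rp.chi2_reduced(data, p)  # n=3 <= k=3

    def test_zero_sigma_replaced_with_warning(self):
        sd = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning):
            out = _safe_sd(sd)
        assert out[0] == 1.0 and np.all(out[1:] == sd[1:])


class TestFit:
    def test_noiseless_recovery_within_one_percent(self, noiseless_curves):
        truth = rp.default_ground_truth()[10.0]
        c = [x for x in noiseless_curves if x.dose == 10.0][-1]
        res = rp.fit(c, n_starts=60, seed=4)
        for name in res.free_names:
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01, abs=2e-5
            ), name

    def test_seeded_determinism(self, curves):
        c = [x for x in curves if x.dose == 15.0][-1]
        r1 = rp.fit(c, n_starts=15, seed=42)
        r2 = rp.fit(c, n_starts=15, seed=42)
        assert r1.chi2_nu == r2.chi2_nu
        np.testing.assert_array_equal(r1.free_values, r2.free_values)
        np.testing.assert_array_equal(r1.start_objectives, r2.start_objectives)

    def test_objective_contraction_and_bounds(self, curves):
        c = [x for x in curves if x.dose == 10.0][-1]
        res = rp.fit(c, n_starts=15, seed=3)
        assert res.chi2_nu <= np.min(res.start_objectives) + 1e-12
        for name, v in zip(res.free_names, res.free_values):
            lo, hi = res.bounds[name]
            assert lo - 1e-12 <= v <= hi + 1e-12

    def test_derived_relations_hold_post_fit(self, curves):
        c = [x for x in curves if x.dose == 5.0][-1]
        res = rp.fit(c, n_starts=10, seed=1)
        p = res.params
        assert p.kd == pytest.approx(p.lambda_u + p.lambda_r - p.gamma)
        assert p.lambda_D == pytest.approx(p.gamma - p.lambda_s)
        assert p.lambda_D >= -1e-12

    def test_control_fit_with_irradiation_model_drives_lambda_u_to_zero(
        self, noiseless_curves
    ):
        # continuity between the irradiated and control models as dose -> 0
        c = [x for x in noiseless_curves if x.dose == 0.0][2]
        res = rp.fit(
            c,
            free_names=("lambda_u", "lambda_r"),
            fixed={"Ta": 0.0, "lambda_s": 0.0},
            n_starts=40,
            seed=8,
            logistic=False,
        )
        assert res.params.lambda_u < 1e-3
        kd = res.params.kd
        assert kd == pytest.approx(0.045, rel=0.02)


class TestTaEstimator:
    def test_recovers_generating_Ta_noiseless(self, noiseless_curves):
        c15 = [x for x in noiseless_curves if x.dose == 15.0]
        est = rp.estimate_Ta(c15)
        assert abs(est - 21.0) <= 1.5

    def test_recovers_Ta_at_experimental_noise(self, curves):
        c15 = [x for x in curves if x.dose == 15.0]
        est = rp.estimate_Ta(c15)
        assert abs(est - 21.0) <= 1.5

    def test_no_curves_rejected(self):
        with pytest.raises(ValueError):
            rp.estimate_Ta([])


class TestGammaFromPeak:
    def test_ratio_of_times(self):
        # Tmax = 35 h, Ta = 18 h -> gamma = 1/17 ~ 0.059
        t = np.arange(0.0, 80.0, 1.0)
        y = np.exp(-((t - 35.0) ** 2) / 200.0)
        c = _course(10.0, 1.0, t, y)
        assert rp.estimate_gamma_from_peak(c, Ta=18.0, window=5) == pytest.approx(
            1 / 17, rel=0.05
        )

    def test_analytic_misrepair_curve_recovers_gamma_exactly(self):
        p = rp.ModelParams(dose=15.0, Ta=21.0, lambda_u=0.12, lambda_r=1e-4, lambda_s=0.02)
        t = np.arange(21.0, 140.0, 0.05)
        Cu = np.asarray(rp.analytic_no_logistic(p, 1.0, t).Cu)
        c = _course(15.0, 1.0, t, Cu)
        est = rp.estimate_gamma_from_peak(c, Ta=21.0, window=5)
        assert est == pytest.approx(0.06, rel=0.01)

    def test_noiseless_high_dose_curve_within_15_percent(self, noiseless_curves):
        # lowest seeding density: the low-density (Cu-dominance) regime where
        # the peak-time relation Tmax = Ta + 1/gamma holds
        c = [x for x in noiseless_curves if x.dose == 10.0][0]
        est = rp.estimate_gamma_from_peak(c, Ta=18.0)
        assert est == pytest.approx(0.06, rel=0.15)

    def test_peak_before_Ta_rejected(self):
        t = np.arange(0.0, 40.0, 1.0)
        y = np.exp(-((t - 10.0) ** 2) / 30.0)
        c = _course(10.0, 1.0, t, y)
        with pytest.raises(ValueError):
            rp.estimate_gamma_from_peak(c, Ta=18.0, window=5)


class TestProfileLikelihood:
    def test_profile_of_true_parameter_minimized_at_truth(self, noiseless_curves):
        c = [x for x in noiseless_curves if x.dose == 10.0][-1]
        grid = np.array([0.02, 0.04, 0.06, 0.08, 0.10])
        pl = rp.profile_likelihood(c, "gamma", grid, n_starts_per_point=25, seed=2)
        assert pl.argmin == pytest.approx(0.06)
        assert pl.chi2_nu_min[2] == np.nanmin(pl.chi2_nu_min)

    def test_lambda_u_profile_on_control_data_approaches_zero(self, noiseless_curves):
        c = [x for x in noiseless_curves if x.dose == 0.0][1]
        grid = np.array([0.0, 1e-3, 1e-2, 0.05, 0.1])
        pl = rp.profile_likelihood(
            c,
            "lambda_u",
            grid,
            n_starts_per_point=20,
            seed=3,
            free_names=("lambda_r",),
            fixed={"Ta": 0.0, "lambda_s": 0.0},
            logistic=False,
        )
        assert pl.argmin == 0.0

    def test_empty_grid_rejected(self, curves):
        with pytest.raises(ValueError):
            rp.profile_likelihood(curves[0], "gamma", [])


class TestExponentialControl:
    def test_noiseless_rate_recovered_exactly(self):
        t = np.arange(0.0, 144.001, 1.5)
        cs = [_course(0.0, 1e-5, t, 1e-5 * np.exp(0.045 * t), idx=i) for i in range(3)]
        assert rp.fit_exponential_control(cs) == pytest.approx(0.045, abs=1e-6)

    def test_matches_log_linear_regression_without_noise(self):
        t = np.arange(0.0, 100.0, 2.0)
        y = 2e-5 * np.exp(0.038 * t)
        c = _course(0.0, 2e-5, t, y)
        slope = np.polyfit(t, np.log(y / y[0]), 1)[0]
        assert rp.fit_exponential_control([c]) == pytest.approx(slope, abs=1e-6)

    def test_noisy_triplicates_within_five_percent(self, curves):
        ctrl = [c for c in curves if c.dose == 0.0]
        assert rp.fit_exponential_control(ctrl) == pytest.approx(0.045, rel=0.05)

    def test_nonpositive_density_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        y = np.ones_like(t)
        y[3] = 0.0
        with pytest.raises(ValueError):
            rp.fit_exponential_control([_course(0.0, 1.0, t, y)])


class TestCsvIO:
    def test_round_trip(self, tmp_path, curves):
        path = tmp_path / "curves.csv"
        rp.write_timecourses(curves[:5], path)
        back = rp.read_timecourses(path)
        assert len(back) == 5
        orig = {(c.dose, c.seeding_index): c for c in curves[:5]}
        for c in back:
            o = orig[(c.dose, c.seeding_index)]
            np.testing.assert_allclose(c.mean_density, o.mean_density)
            np.testing.assert_allclose(c.sd_density, o.sd_density)
            assert c.C0 == pytest.approx(o.C0, rel=1e-12)
            assert c.n_replicates == o.n_replicates

    def test_default_ta_table(self):
        assert TA_BY_DOSE == {0.0: 0.0, 5.0: 16.0, 10.0: 18.0, 15.0: 21.0}
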