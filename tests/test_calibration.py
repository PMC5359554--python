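"""Objective function, one-at-a-time sensitivity, and parameter fitting."""

import numpy as np
import pytest

import tlksim as t
from tlksim.calibration import (
    SurvivalCurveData,
    objective,
    read_survival_curve,
    sensitivity_scan,
    write_survival_curve,
)
from tlksim.errors import ValidationError


class StubConfig:
    """Deterministic stand-in whose simulated curve is a fixed array."""

    def __init__(self, sf):
        self._sf = np.asarray(sf, dtype=float)

    def simulated_sf(self, params, doses):
        return self._sf


class TestObjective:
    def test_perfect_fit_scores_zero(self, truth_params):
        data = SurvivalCurveData(np.array([1.0, 2.0]), np.array([0.5, 0.25]))
        assert objective(truth_params, data, StubConfig([0.5, 0.25])) == 0.0

    def test_factor_ten_contributes_one(self, truth_params):
        data = SurvivalCurveData(np.array([1.0, 2.0]), np.array([0.5, 0.25]))
        got = objective(truth_params, data, StubConfig([0.5, 0.025]))
        assert got == pytest.approx(1.0, rel=1e-12)

    def test_matches_term_by_term_oracle(self, truth_params):
        rng = np.random.default_rng(21)
        n = 8
        meas = rng.uniform(0.01, 1.0, n)
        sim = rng.uniform(0.01, 1.0, n)
        data = SurvivalCurveData(np.arange(1.0, n + 1), meas)
        got = objective(truth_params, data, StubConfig(sim))
        want = sum((np.log10(s) - np.log10(m)) ** 2 for s, m in zip(sim, meas))
        assert got == pytest.approx(want, rel=1e-12)

    def test_order_invariance(self, truth_params):
        doses = np.array([1.0, 2.0, 3.0])
        meas = np.array([0.9, 0.5, 0.2])
        sim = np.array([0.8, 0.4, 0.3])
        a = objective(truth_params, SurvivalCurveData(doses, meas), StubConfig(sim))
        b = objective(
            truth_params,
            SurvivalCurveData(doses[::-1].copy(), meas[::-1].copy()),
            StubConfig(sim[::-1].copy()),
        )
        assert a == pytest.approx(b, rel=1e-14)

    def test_linear_scale_option(self, truth_params):
        data = SurvivalCurveData(np.array([1.0]), np.array([0.5]))
        got = objective(truth_params, data, StubConfig([0.4]), scale="linear")
        assert got == pytest.approx(0.01, rel=1e-12)

    def test_zero_simulated_sf_rejected(self, truth_params):
        data = SurvivalCurveData(np.array([1.0]), np.array([0.5]))
        with pytest.raises(ValidationError, match="zero"):
            objective(truth_params, data, StubConfig([0.0]))


class TestSensitivity:
    def test_ignored_parameter_scans_flat(self, cal_config, truth_params, doses6):
        p = truth_params.replace(eta_per_h=0.0)
        curve = t.make_survival_curve(cal_config, p, doses6)
        scan = sensitivity_scan(curve, cal_config, p, "lethal_pair_frac",
                                factors=np.logspace(-1, 0.6, 4))
        assert scan.range == 0.0

    def test_eta_outranks_beta1_on_packaged_fixture(self, cal_config, truth_params,
                                                    doses6):
        curve = t.make_survival_curve(cal_config, truth_params, doses6)
        r = {
            name: sensitivity_scan(curve, cal_config, truth_params, name).range
            for name in ("beta1", "eta_per_h")
        }
        assert r["eta_per_h"] > r["beta1"]

    def test_scan_minimum_at_generator_value(self, cal_config, truth_params, doses6):
        curve = t.make_survival_curve(cal_config, truth_params, doses6)
        scan = sensitivity_scan(curve, cal_config, truth_params, "eta_per_h")
        i_base = int(np.argmin(np.abs(scan.values - truth_params.eta_per_h)))
        assert int(np.argmin(scan.obj)) == i_base
        assert scan.obj[i_base] == pytest.approx(0.0, abs=1e-20)

    def test_probability_grid_clipped_to_validity(self, cal_config, truth_params,
                                                  doses6):
        curve = t.make_survival_curve(cal_config, truth_params, doses6)
        scan = sensitivity_scan(curve, cal_config, truth_params, "beta2")
        assert np.all(scan.values <= 1.0)

    def test_degenerate_grid_rejected(self, cal_config, truth_params, doses6):
        curve = t.make_survival_curve(cal_config, truth_params, doses6)
        with pytest.raises(ValidationError):
            sensitivity_scan(curve, cal_config, truth_params, "eta_per_h",
                             factors=[1.0])


class TestCalibrate:
    def test_starting_guess_fixed_point(self, cal_config, doses6):
        start = t.TLKParams(beta1=1e-3, beta2=5e-3, eta_per_h=1e-5)
        curve = t.make_survival_curve(cal_config, start, doses6)
        res = t.calibrate(curve, cal_config, initial=start)
        assert res.obj_value <= 1e-12
        for name in ("beta1", "beta2", "eta_per_h"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(start, name), rel=0.05
            )

    def test_noisy_recovery_of_identifiable_quantities(self, cal_config,
                                                       truth_params, doses6):
        # Under multiplicative noise the two linear lethality probabilities
        # are only weakly separable: both scale lesion pools that grow
        # proportionally with dose, so the strongly identified quantities
        # are eta (it alone bends the curve quadratically) and the combined
        # linear lethality rate beta1*L1/Gy + beta2*L2/Gy.
        curve = t.make_survival_curve(cal_config, truth_params, doses6,
                                      noise=0.03, seed=17)
        res = t.calibrate(curve, cal_config)

        fit_eta = np.log10(res.params.eta_per_h)
        true_eta = np.log10(truth_params.eta_per_h)
        assert abs(fit_eta - true_eta) / abs(true_eta) < 0.25

        pop = cal_config.population
        a, b = pop.l1_per_gy.mean(), pop.l2_per_gy.mean()

        def linear_lethality(p):
            return p.beta1 * a + p.beta2 * b

        assert linear_lethality(res.params) == pytest.approx(
            linear_lethality(truth_params), rel=0.25
        )
        # objective lands at (or below) the noise floor and never exceeds
        # the score of the generating parameters
        noise_floor = 6 * (0.03 / np.log(10)) ** 2
        truth_obj = t.objective(truth_params, curve, cal_config)
        assert res.obj_value < 3 * noise_floor
        assert res.obj_value <= truth_obj
        # never worse than the initial guess
        assert res.trace[0][1] >= res.obj_value

    def test_bad_bounds_rejected(self, cal_config, truth_params, doses6):
        curve = t.make_survival_curve(cal_config, truth_params, doses6)
        with pytest.raises(ValidationError):
            t.calibrate(curve, cal_config, bounds={"beta1": (0.5, 1e-5)})


class TestCurveIO:
    def test_roundtrip(self, tmp_path):
        data = SurvivalCurveData(
            np.array([0.1, 1.0, 5.0]), np.array([0.99, 0.8, 0.2]),
            np.array([0.01, 0.02, 0.03]),
        )
        path = tmp_path / "curve.csv"
        write_survival_curve(data, path)
        back = read_survival_curve(path)
        np.testing.assert_allclose(back.doses_gy, data.doses_gy)
        np.testing.assert_allclose(back.sf, data.sf)
        np.testing.assert_allclose(back.sf_err, data.sf_err)

    @pytest.mark.parametrize("doses,sf", [
        ([1.0], [0.0]), ([1.0], [1.5]), ([-1.0], [0.5]),
    ])
    def test_invalid_curves_rejected(self, doses, sf):
        with pytest.raises(ValidationError):
            SurvivalCurveData(np.array(doses), np.array(sf))
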