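"""Time-course extrapolation, schedule fitting, objective and estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from rootniche.defaults import CANONICAL_FPKM_5D, default_parameter_set
from rootniche.errors import (
    CalibrationError,
    ConfigurationError,
    IncompleteGridError,
)
from rootniche.fitting import (
    OBJECTIVE_SENTINEL,
    TimeCourse,
    calibrate_thresholds,
    estimate_parameters,
    extrapolate_timecourse,
    fit_production_schedule,
    initial_state_from_timecourse,
    objective,
)
from rootniche.model import SCHEDULE_GRID, build_model
from rootniche.simulate import Trajectory
from rootniche.synthetic import SyntheticSpec, generate_ground_truth_run

GRID = list(SCHEDULE_GRID)


def _foldchanges(series, species="WOX5"):
    return {(species, t): v for t, v in zip(GRID, series)}


class TestExtrapolation:
    def test_unit_foldchanges_give_constant_series(self):
        tc = extrapolate_timecourse(
            {("WOX5", "QC"): 10.0}, _foldchanges([1.0] * 7)
        )
        np.testing.assert_allclose(tc.series("WOX5", "QC"), 10.0)

    def test_hand_computed_series(self):
        fc = _foldchanges([0.5, 0.8, 1.0, 1.0, 1.2, 1.5, 1.0])
        tc = extrapolate_timecourse({("WOX5", "QC"): 10.0}, fc)
        np.testing.assert_allclose(
            tc.series("WOX5", "QC"), [5.0, 8.0, 10.0, 10.0, 12.0, 15.0, 10.0]
        )

    def test_five_day_anchor_is_exact(self):
        fc = _foldchanges([0.7, 0.9, 2.0, 1.0, 1.1, 1.3, 0.8])
        # non-unit anchor values renormalise away
        fc = {k: v * 3.7 for k, v in fc.items()}
        tc = extrapolate_timecourse({("WOX5", "QC"): 12.5}, fc)
        assert tc.value("WOX5", "QC", 120.0) == pytest.approx(12.5)

    def test_zero_fpkm_propagates(self):
        tc = extrapolate_timecourse(
            {("WOX5", "QC"): 0.0}, _foldchanges([0.5, 1, 1, 1, 1, 1, 1])
        )
        np.testing.assert_array_equal(tc.series("WOX5", "QC"), 0.0)

    def test_missing_grid_point_rejected(self):
        fc = _foldchanges([1.0] * 6 + [1.0])
        del fc[("WOX5", 128.0)]
        with pytest.raises(IncompleteGridError):
            extrapolate_timecourse({("WOX5", "QC"): 10.0}, fc)


class TestScheduleFitting:
    def test_steady_state_balance(self, plain_wt_model):
        """A flat target X* requires the constant rate d_eff * X* everywhere."""
        target = 20.0
        p = plain_wt_model.params
        deff = p["d1_qc"] + p["b_qc"] + p["b_cei"]
        tc = extrapolate_timecourse({("WOX5", "QC"): target}, _foldchanges([1.0] * 7))
        rates = fit_production_schedule(plain_wt_model, "WOX5", tc)["k1_qc"]
        np.testing.assert_allclose(rates, deff * target, rtol=1e-12)

    def test_known_schedule_recovered_via_ode_oracle(self, plain_wt_model):
        """Data generated by integrating a known stepwise schedule is refitted
        to that schedule within 1% (independent solve_ivp oracle)."""
        p = plain_wt_model.params
        deff = p["d1_qc"] + p["b_qc"] + p["b_cei"]
        true = np.array([4.0, 9.0, 2.0, 7.0, 1.0, 6.0, 6.0])

        def rhs(t, y):
            i = min(int((t - 96.0) // 8.0), 6)
            return true[i] - deff * y[0]

        sol = solve_ivp(rhs, (96.0, 144.0), [15.0], t_eval=GRID, rtol=1e-10, atol=1e-12)
        tc = TimeCourse(
            pd.DataFrame(
                {
                    "species": "WOX5",
                    "cell_type": "QC",
                    "time_h": GRID,
                    "fpkm": sol.y[0],
                }
            )
        )
        rates = fit_production_schedule(plain_wt_model, "WOX5", tc)["k1_qc"]
        np.testing.assert_allclose(rates[:6], true[:6], rtol=0.01)

    def test_negative_optimum_clipped_with_warning(self, plain_wt_model):
        # an abrupt fall faster than free decay needs a negative rate
        series = [50.0, 0.001, 50.0, 50.0, 50.0, 50.0, 50.0]
        tc = extrapolate_timecourse({("WOX5", "QC"): 50.0}, _foldchanges([s / 50 for s in series]))
        with pytest.warns(UserWarning, match="clipped"):
            rates = fit_production_schedule(plain_wt_model, "WOX5", tc)["k1_qc"]
        assert rates[0] == 0.0
        assert np.all(rates >= 0.0)

    def test_all_zero_data_gives_zero_schedule(self, plain_wt_model):
        tc = extrapolate_timecourse({("AN3", "QC"): 0.0, ("AN3", "CEI"): 0.0,
                                     ("AN3", "ENDO"): 0.0},
                                    _foldchanges([1.0] * 7, "AN3"))
        for rates in fit_production_schedule(plain_wt_model, "AN3", tc).values():
            np.testing.assert_array_equal(rates, 0.0)


@pytest.fixture(scope="module")
def truth_run():
    """Noise-free forward-simulated ground truth."""
    spec = SyntheticSpec(seed=3, noise_sigma=0.0)
    model, data = generate_ground_truth_run(spec)
    init = initial_state_from_timecourse(model, data, 96.0)
    return model, data, init


class TestObjective:
    def test_objective_vanishes_at_truth(self, truth_run):
        model, data, init = truth_run
        names = ["k4_vasc", "d3_qc"]
        f = objective([model.params[n] for n in names], model, data, names, init=init)
        assert f < 1e-4

    @pytest.mark.parametrize("name", ["k4_vasc", "d3_qc", "k5_cei"])
    def test_perturbation_increases_objective(self, truth_run, name):
        model, data, init = truth_run
        f0 = objective([model.params[name]], model, data, [name], init=init)
        f1 = objective([model.params[name] * 1.5], model, data, [name], init=init)
        assert f1 > f0

    def test_blowup_returns_sentinel(self, truth_run):
        model, data, init = truth_run
        f = objective([1e12], model, data, ["k4_vasc"], init=init)
        assert f == OBJECTIVE_SENTINEL or np.isfinite(f)

    def test_mismatched_lengths_rejected(self, truth_run):
        model, data, init = truth_run
        with pytest.raises(ConfigurationError):
            objective([1.0, 2.0], model, data, ["k4_vasc"], init=init)


class TestEstimation:
    def test_single_run_mean_is_that_run(self, truth_run):
        model, data, init = truth_run
        est = estimate_parameters(
            model, data, ["d3_qc"], n_runs=1, seed=7, init=init,
            n_temps=5, iters_per_temp=5, rtol=1e-4, atol=1e-7,
        )
        np.testing.assert_array_equal(est.mean, est.runs[0])

    def test_two_parameter_recovery_noise_free(self, truth_run):
        """Annealing from LHS starts recovers a 2-parameter truth within 10%
        on noise-free synthetic data."""
        model, data, init = truth_run
        names = ["k4_vasc", "d3_qc"]
        est = estimate_parameters(
            model, data, names, n_runs=6, seed=0, init=init,
            n_temps=30, iters_per_temp=15, rtol=1e-4, atol=1e-7,
        )
        truth = np.array([model.params[n] for n in names])
        assert np.all(np.abs(est.mean - truth) / truth < 0.10)
        assert np.all(est.runs >= est.bounds[:, 0]) and np.all(
            est.runs <= est.bounds[:, 1]
        )

    def test_empty_free_names_rejected(self, truth_run):
        model, data, init = truth_run
        with pytest.raises(ConfigurationError):
            estimate_parameters(model, data, [], n_runs=1, seed=0, init=init)


class TestCalibrateThresholds:
    def _trajectory(self, model, cyc, ssc, wox):
        n = len(cyc)
        times = np.linspace(96.0, 144.0, n)
        states = np.zeros((n, model.n_states))
        states[:, model.index("CEI", "CYCD6")] = cyc
        states[:, model.index("QC", "SSC")] = ssc
        states[:, model.index("QC", "WOX5")] = wox
        return Trajectory(times=times, states=states, events=[], variant=model.variant, model=model)

    def test_flat_trace_is_infeasible(self, plain_wt_model):
        t = np.linspace(96, 144, 50)
        with pytest.raises(CalibrationError):
            calibrate_thresholds(
                self._trajectory(plain_wt_model, np.full(50, 5.0), np.full(50, 5.0), np.full(50, 5.0))
            )

    def test_two_peak_trace_threshold_between_valley_and_lower_peak(self, plain_wt_model):
        t = np.linspace(96.0, 144.0, 200)
        cyc = 10 + 8 * np.exp(-0.5 * ((t - 106) / 4) ** 2) + 12 * np.exp(
            -0.5 * ((t - 134) / 4) ** 2
        )
        ssc = 5 + 10 * np.exp(-0.5 * ((t - 130) / 6) ** 2)
        wox = 30 - 20 * np.exp(-0.5 * ((t - 130) / 8) ** 2)
        rules = calibrate_thresholds(self._trajectory(plain_wt_model, cyc, ssc, wox))
        valley = cyc[(t > 110) & (t < 130)].min()
        lower_peak = 18.0
        assert valley < rules.theta_cycd6 < lower_peak
        assert 5.0 < rules.theta_ssc_qc < 15.0

    def test_recalibration_is_idempotent(self, wt_scenario):
        rules_again = calibrate_thresholds(wt_scenario.free_trajectory)
        assert rules_again.theta_cycd6 == pytest.approx(wt_scenario.rules.theta_cycd6)
        assert rules_again.theta_ssc_qc == pytest.approx(wt_scenario.rules.theta_ssc_qc)

    def test_wt_refractory_zero_x_refractory_sixteen(self, wt_scenario, x_scenario):
        assert wt_scenario.rules.refractory_cei == 0.0
        assert x_scenario.rules.refractory_cei == 16.0
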