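"""Estimation engine: realization sampling, stepping, ensembles, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mingled.network as net
from mingled import (
    AdaptConfig,
    GroundTruthSpec,
    LongitudinalDataset,
    ObservableSeries,
    generate_ground_truth,
    run,
    sample_realization,
    summarize,
)
from mingled.adapt import initialize, step_estimate
from mingled.exceptions import ConfigurationError
from mingled.reference import reference_parameters

from oracles import percentile_oracle


def make_dataset(mean, sd, times=(0.0, 98.0, 196.0), observable="plasma_tg"):
    times = np.asarray(times, dtype=float)
    series = {
        observable: ObservableSeries(
            observable=observable,
            constraint_class="longitudinal",
            times=times,
            mean=np.full(times.size, mean),
            sd=np.full(times.size, sd),
            n=np.full(times.size, 10),
        )
    }
    return LongitudinalDataset(group="responder", series=series).validate()


class TestSampling:
    def test_zero_sd_reproduces_means_exactly(self, rng):
        ds = make_dataset(2.5, 0.0)
        real = sample_realization(ds, rng, AdaptConfig())
        for t in (0.0, 50.0, 98.0, 196.0):
            assert real.value("plasma_tg", t) == pytest.approx(2.5, abs=1e-12)

    def test_interpolant_passes_through_sampled_knots(self, rng):
        ds = make_dataset(2.5, 0.5, times=(0.0, 30.0, 90.0, 150.0, 196.0))
        cfg = AdaptConfig(seed=1)
        r = np.random.default_rng(7)
        draws = np.maximum(r.normal(2.5, 0.5, size=5), 0.0)
        real = sample_realization(ds, np.random.default_rng(7), cfg)
        for t, v in zip((0.0, 30.0, 90.0, 150.0, 196.0), draws):
            assert real.value("plasma_tg", t) == pytest.approx(v, abs=1e-9)

    def test_single_time_point_gives_constant_curve(self, rng):
        series = {
            "plasma_tg": ObservableSeries(
                "plasma_tg", "longitudinal", [0.0], [2.0], [0.0], [5]
            )
        }
        ds = LongitudinalDataset(group="responder", series=series).validate()
        with pytest.warns(UserWarning, match="fewer than 2"):
            real = sample_realization(ds, rng, AdaptConfig())
        assert real.value("plasma_tg", 0.0) == real.value("plasma_tg", 180.0) == 2.0

    def test_sampling_distribution_at_a_knot(self):
        ds = make_dataset(5.0, 0.5, times=(0.0, 196.0))
        rng = np.random.default_rng(3)
        cfg = AdaptConfig()
        draws = np.array(
            [sample_realization(ds, rng, cfg).value("plasma_tg", 0.0) for _ in range(10_000)]
        )
        se_mean = 0.5 / np.sqrt(10_000)
        assert abs(draws.mean() - 5.0) < 3 * se_mean
        se_sd = 0.5 / np.sqrt(2 * (10_000 - 1))
        assert abs(draws.std(ddof=1) - 0.5) < 3 * se_sd


class TestInitialize:
    def test_recovers_steady_state_observables(self, model):
        spec = GroundTruthSpec(noise_cv=0.0)
        ds, _ = generate_ground_truth(spec, model, np.random.default_rng(0))
        cfg = AdaptConfig()
        real = sample_realization(ds, np.random.default_rng(0), cfg)
        theta, x, resid = initialize(real, model, cfg)
        names = list(real.series)
        ev = model.observable_evaluator(names)
        y = ev(x, model._fluxes_unchecked(x, theta), theta)
        targets = np.array([real.value(n, 0.0) for n in names])
        assert np.all(np.abs(y - targets) <= 0.01 * np.abs(targets) + 1e-9)

    def test_zero_targets_zero_diet_gives_zero_solution(self, model):
        from mingled import Model

        m0 = Model(forcings={f: 0.0 for f in net.FORCINGS})
        ds = make_dataset(0.0, 0.0)
        cfg = AdaptConfig(n_restarts=1, prior_weight=0.0)
        real = sample_realization(ds, np.random.default_rng(0), cfg)
        theta, x, resid = initialize(real, m0, cfg)
        assert np.allclose(x, 0.0, atol=1e-6)
        assert resid == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_targets_leave_positive_residual(self, model):
        # TC below HDL-C cannot be realized (TC = VLDL-C + HDL-C >= HDL-C)
        times = np.array([0.0, 196.0])
        mk = lambda name, val: ObservableSeries(
            name, "longitudinal", times, np.full(2, val), np.full(2, 0.05 * val), [10, 10]
        )
        ds = LongitudinalDataset(
            group="responder",
            series={"plasma_tc": mk("plasma_tc", 1.0), "plasma_hdl_c": mk("plasma_hdl_c", 2.0)},
        ).validate()
        cfg = AdaptConfig(n_restarts=2)
        real = sample_realization(ds, np.random.default_rng(0), AdaptConfig())
        theta, x, resid = initialize(real, model, cfg)
        assert resid > 1.0
        obs = model.observables(x, params=theta)
        assert obs["plasma_tc"] >= obs["plasma_hdl_c"] - 1e-9


class TestStepEstimate:
    def test_huge_penalty_freezes_parameters(self, model, ref_params):
        spec = GroundTruthSpec(noise_cv=0.05)
        ds, _ = generate_ground_truth(spec, model, np.random.default_rng(1))
        cfg = AdaptConfig()
        real = sample_realization(ds, np.random.default_rng(1), cfg)
        theta_prev = np.array([ref_params[p] for p in net.PARAMETERS])
        x_prev = model.solve_steady_state(theta_prev)
        theta, _, _ = step_estimate(
            model, theta_prev, x_prev, real, 0.0, 3.92, lam=1e9, config=cfg
        )
        assert np.allclose(theta, theta_prev, rtol=1e-6, atol=1e-12)

    def test_step_improves_on_warm_start_objective(self, model, ref_params):
        """The returned parameters must not be worse than staying at the
        previous parameters under the same objective (lambda = 0)."""
        spec = GroundTruthSpec(
            drift={"k_vldl_tg_production": ((0.0, 1.0), (196.0, 0.7))}, noise_cv=0.05
        )
        ds, _ = generate_ground_truth(spec, model, np.random.default_rng(2))
        cfg = AdaptConfig()
        real = sample_realization(ds, np.random.default_rng(2), cfg)
        theta_prev = np.array([ref_params[p] for p in net.PARAMETERS])
        x_prev = model.solve_steady_state(theta_prev)

        def data_misfit(theta):
            x = np.maximum(model.propagate(x_prev, theta, 98.0), 0.0)
            j = model._fluxes_unchecked(x, theta)
            names = [n for n, s in real.series.items() if s.active(98.0)]
            ev = model.observable_evaluator(names)
            res = (ev(x, j, theta) - np.array([real.value(n, 98.0) for n in names])) / np.array(
                [real.series[n].sigma(98.0) for n in names]
            )
            return float(np.sum(res**2))

        theta, _, misfit = step_estimate(
            model, theta_prev, x_prev, real, 0.0, 98.0, lam=0.0, config=cfg
        )
        assert misfit <= data_misfit(theta_prev) + 1e-9
        assert misfit == pytest.approx(data_misfit(theta), rel=1e-9, abs=1e-12)

    def test_constant_truth_recovered_across_steps(self, model, ref_params):
        """Data simulated with constant parameters: estimates stay within 5%
        of the truth and steps change parameters by far less than 1%."""
        spec = GroundTruthSpec(noise_cv=0.0)
        ds, _ = generate_ground_truth(spec, model, np.random.default_rng(3))
        cfg = AdaptConfig(n_steps=10, n_iterations=1, seed=4)
        res = run(ds, model, cfg)
        truth = np.array([ref_params[p] for p in net.PARAMETERS])
        rel_dev = np.abs(res.params[0] - truth[:, None]) / truth[:, None]
        assert rel_dev.max() < 0.05
        step_change = np.abs(np.diff(res.params[0], axis=1)) / truth[:, None]
        assert step_change.max() < 0.01


class TestRun:
    def test_deterministic_under_fixed_seed(self, model):
        spec = GroundTruthSpec(
            drift={"k_vldl_tg_production": ((0.0, 1.0), (196.0, 0.7))}, noise_cv=0.05
        )
        ds, _ = generate_ground_truth(spec, model, np.random.default_rng(6))
        cfg = AdaptConfig(n_steps=5, n_iterations=2, seed=11)
        r1 = run(ds, model, cfg)
        r2 = run(ds, model, cfg)
        assert np.array_equal(r1.params, r2.params)
        assert np.array_equal(r1.states, r2.states)
        assert np.array_equal(r1.fluxes, r2.fluxes)
        med1, lo1, hi1 = summarize(r1.quantity("plasma_tg"))
        med2, lo2, hi2 = summarize(r2.quantity("plasma_tg"))
        assert np.array_equal(med1, med2) and np.array_equal(lo1, lo2)

    def test_regularization_dampens_and_misfit_grows(self, model):
        """Stronger regularization yields smoother parameter trajectories in
        aggregate and a worse total data fit."""
        spec = GroundTruthSpec(
            drift={"k_vldl_tg_production": ((0.0, 1.0), (196.0, 0.7))}, noise_cv=0.05
        )
        ds, _ = generate_ground_truth(spec, model, np.random.default_rng(42))
        ref = np.array([reference_parameters()[p] for p in net.PARAMETERS])
        agg_tv, misfit = [], []
        for lam in (0.01, 1.0, 100.0):
            r = run(ds, model, AdaptConfig(n_steps=12, n_iterations=1, seed=7, lam=lam))
            tv = np.sum(np.abs(np.diff(r.params[0], axis=1)), axis=1)
            agg_tv.append(float(np.sum(tv / ref)))
            misfit.append(r.total_misfit())
        assert agg_tv[0] >= agg_tv[1] >= agg_tv[2]
        assert misfit[0] <= misfit[1] <= misfit[2]


class TestSummarize:
    def test_single_trajectory_degenerate_band(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        med, lo, hi = summarize(vals)
        assert np.array_equal(med, vals[0])
        assert np.array_equal(lo, vals[0]) and np.array_equal(hi, vals[0])

    def test_hundred_constant_trajectories_percentiles(self):
        vals = np.arange(1.0, 101.0)[:, None]
        med, lo, hi = summarize(vals)
        assert med[0] == pytest.approx(50.5)
        assert lo[0] == pytest.approx(35.65)
        assert hi[0] == pytest.approx(65.35)

    def test_band_matches_brute_force_percentile_oracle(self, rng):
        vals = rng.normal(size=(37, 4))
        med, lo, hi = summarize(vals)
        for t in range(4):
            assert med[t] == pytest.approx(percentile_oracle(vals[:, t], 50.0), rel=1e-12)
            assert lo[t] == pytest.approx(percentile_oracle(vals[:, t], 35.0), rel=1e-12)
            assert hi[t] == pytest.approx(percentile_oracle(vals[:, t], 65.0), rel=1e-12)

    def test_symmetric_ensemble_gives_symmetric_band(self):
        vals = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        med, lo, hi = summarize(vals)
        assert med[0] == 0.0
        assert lo[0] == pytest.approx(-hi[0])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize(np.empty((0, 3)))

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
    )
    def test_band_brackets_median(self, values):
        med, lo, hi = summarize(np.asarray(values)[:, None])
        assert lo[0] <= med[0] <= hi[0]

    def test_median_fraction_convention(self):
        vals = np.array([[10.0], [20.0], [30.0]])
        med, lo, hi = summarize(vals, band="median_fraction")
        assert med[0] == 20.0 and lo[0] == pytest.approx(14.0) and hi[0] == pytest.approx(26.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [{"n_steps": 1}, {"lam": -0.1}, {"n_iterations": 0}, {"spline": "sinc"}],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            AdaptConfig(**kwargs)
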