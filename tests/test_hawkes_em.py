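import numpy as np
import pytest

from hothand.hawkes_em import (
    ExponentialKernel,
    HawkesModel,
    HistogramKernel,
    ZeroKernel,
    branching_ratio,
    em_fit,
    intensity,
    loglik,
    residual_gof,
)
from hothand.synthetic_data import simulate_hawkes


def unit_kernel():
    return HistogramKernel(np.asarray([0.0, 2.0]), np.asarray([0.5]))


class TestIntensity:
    def test_single_event_within_support(self):
        model = HawkesModel(mu=1.0, kernel=unit_kernel())
        assert intensity(model, [1.0], 2.0) == pytest.approx(1.5)

    def test_lag_beyond_support(self):
        model = HawkesModel(mu=1.0, kernel=unit_kernel())
        assert intensity(model, [1.0], 4.0) == pytest.approx(1.0)

    def test_empty_history_is_background(self):
        model = HawkesModel(mu=0.7, kernel=unit_kernel())
        assert intensity(model, [], 3.3) == pytest.approx(0.7)

    def test_unsorted_history_rejected(self):
        model = HawkesModel(mu=1.0, kernel=unit_kernel())
        with pytest.raises(ValueError, match="sorted"):
            intensity(model, [2.0, 1.0], 3.0)


class TestLoglik:
    def test_poisson_closed_form(self):
        model = HawkesModel(mu=2.0, kernel=ZeroKernel())
        value = loglik(model, [0.5, 1.0], (0.0, 2.0))
        assert value == pytest.approx(2 * np.log(2.0) - 4.0, abs=1e-12)

    def test_empty_window_is_minus_mu_T(self):
        model = HawkesModel(mu=1.7, kernel=ZeroKernel())
        assert loglik(model, [], (0.0, 3.0)) == pytest.approx(-1.7 * 3.0, abs=1e-12)

    def test_compensator_matches_quadrature(self, rng):
        kernel = HistogramKernel(
            np.asarray([0.0, 0.3, 0.8, 1.5]), np.asarray([0.9, 0.4, 0.1])
        )
        model = HawkesModel(mu=0.8, kernel=kernel)
        events = np.sort(rng.uniform(0.1, 4.9, size=12))
        a, b = 0.0, 5.0

        def lam(s):
            past = events[events < s]
            return model.mu + kernel.value(s - past).sum()

        # lambda(s) is a step function with breakpoints at t_i + e_b, so
        # midpoint integration over those segments is exact
        breaks = np.unique(np.concatenate(
            [[a, b]] + [events + e for e in kernel.edges]
        ))
        breaks = breaks[(breaks >= a) & (breaks <= b)]
        mids = (breaks[:-1] + breaks[1:]) / 2
        integral = float(np.sum([lam(m) for m in mids] * np.diff(breaks)))
        # lam(t_i) excludes t_i itself (strictly earlier events only)
        expected = sum(np.log(lam(t)) for t in events) - integral
        assert loglik(model, events, (a, b)) == pytest.approx(expected, abs=1e-8)

    def test_conditioning_history_contributes_excitation(self):
        model = HawkesModel(mu=1.0, kernel=unit_kernel())
        with_hist = loglik(model, [1.5], (1.0, 2.0), history=[0.9])
        without = loglik(model, [1.5], (1.0, 2.0))
        assert with_hist != without
        # lambda(1.5) = mu + phi(0.6) = 1.5; the compensator over (1, 2] is
        # mu*1 + [Phi(1.1) - Phi(0.1)] from the history event at 0.9 plus
        # Phi(0.5) from the in-window event at 1.5 = 1 + 0.5 + 0.25
        assert with_hist == pytest.approx(np.log(1.5) - 1.75, abs=1e-12)

    def test_zero_intensity_event_is_degenerate(self):
        model = HawkesModel(mu=0.0, kernel=ZeroKernel())
        assert loglik(model, [0.5], (0.0, 1.0)) == -np.inf

    def test_history_after_window_start_rejected(self):
        model = HawkesModel(mu=1.0, kernel=ZeroKernel())
        with pytest.raises(ValueError, match="history"):
            loglik(model, [1.5], (1.0, 2.0), history=[1.2])


class TestBranchingRatio:
    def test_histogram_integral(self):
        kernel = HistogramKernel(np.asarray([0.0, 2.0, 4.0]), np.asarray([0.1, 0.05]))
        assert branching_ratio(HawkesModel(1.0, kernel)) == pytest.approx(0.3)

    def test_zero_kernel(self):
        assert branching_ratio(HawkesModel(1.0, ZeroKernel())) == 0.0

    def test_matches_numerical_integration(self):
        kernel = HistogramKernel(
            np.asarray([0.0, 0.7, 1.1, 3.0]), np.asarray([0.33, 0.21, 0.04])
        )
        # midpoint rule on segments nested inside bins is exact for a step
        # function, so agreement is to machine precision
        numeric = 0.0
        for lo, hi in zip(kernel.edges[:-1], kernel.edges[1:]):
            grid = np.linspace(lo, hi, 1001)
            mids = (grid[:-1] + grid[1:]) / 2
            numeric += float(np.sum(kernel.value(mids) * np.diff(grid)))
        assert kernel.integral == pytest.approx(numeric, abs=1e-12)


class TestEmFit:
    def test_poisson_data_gives_small_branching(self):
        ns, mus = [], []
        for s in range(8):
            events = simulate_hawkes(1.0, ZeroKernel(), 2000.0, seed=s)
            res = em_fit(events, 2000.0)
            ns.append(res.branching_ratio)
            mus.append(res.model.mu)
        assert np.median(ns) < 0.15
        assert 0.85 <= np.median(mus) <= 1.15

    def test_recovers_branching_ratio(self):
        ns = []
        for s in range(8):
            events = simulate_hawkes(1.0, ExponentialKernel(0.5, 1.0), 2000.0, seed=s)
            ns.append(em_fit(events, 2000.0).branching_ratio)
        assert abs(np.median(ns) - 0.5) < 0.1

    def test_loglik_trace_monotone(self):
        events = simulate_hawkes(1.0, ExponentialKernel(0.4, 0.5), 300.0, seed=2)
        res = em_fit(events, 300.0)
        assert np.all(np.diff(res.loglik_trace) >= -1e-9)
        assert res.converged

    def test_deterministic_given_inputs(self):
        events = simulate_hawkes(1.0, ExponentialKernel(0.3, 1.0), 200.0, seed=4)
        r1 = em_fit(events, 200.0)
        r2 = em_fit(events, 200.0)
        np.testing.assert_array_equal(r1.model.kernel.heights, r2.model.kernel.heights)
        assert r1.model.mu == r2.model.mu

    def test_beats_homogeneous_poisson_mle(self):
        events = simulate_hawkes(1.0, ExponentialKernel(0.5, 1.0), 500.0, seed=6)
        res = em_fit(events, 500.0)
        fitted_ll = loglik(res.model, events, (0.0, 500.0))
        poisson_mle = HawkesModel(mu=events.size / 500.0, kernel=ZeroKernel())
        assert fitted_ll >= loglik(poisson_mle, events, (0.0, 500.0)) - 1e-6

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            em_fit(np.linspace(0.1, 1.0, 5), 1.0)

    def test_non_convergence_is_flagged_not_raised(self):
        events = simulate_hawkes(1.0, ExponentialKernel(0.5, 1.0), 500.0, seed=7)
        res = em_fit(events, 500.0, max_iter=2)
        assert not res.converged
        assert res.iterations == 2


class TestResidualGof:
    def test_true_model_calibration(self):
        # exact model on its own simulation: KS p should be roughly uniform
        rejections = 0
        n_seeds = 60
        for s in range(n_seeds):
            mu, kernel = 1.0, ExponentialKernel(0.4, 1.0)
            events = simulate_hawkes(mu, kernel, 400.0, seed=100 + s)
            _, _, p = residual_gof(HawkesModel(mu, kernel), events, 400.0)
            rejections += p < 0.05
        assert 0.0 <= rejections / n_seeds <= 0.12

    def test_poisson_null_model_calibration(self):
        rejections = 0
        n_seeds = 60
        for s in range(n_seeds):
            events = simulate_hawkes(2.0, ZeroKernel(), 300.0, seed=200 + s)
            _, _, p = residual_gof(HawkesModel(2.0, ZeroKernel()), events, 300.0)
            rejections += p < 0.05
        assert 0.0 <= rejections / n_seeds <= 0.12

    def test_wrong_model_is_rejected_often(self):
        rejections = 0
        n_seeds = 30
        for s in range(n_seeds):
            events = simulate_hawkes(1.0, ExponentialKernel(0.6, 0.5), 400.0, seed=300 + s)
            wrong = HawkesModel(mu=0.5, kernel=ZeroKernel())
            _, _, p = residual_gof(wrong, events, 400.0)
            rejections += p < 0.05
        assert rejections / n_seeds > 0.5

    def test_rescaled_gaps_are_positive(self):
        events = simulate_hawkes(1.0, ExponentialKernel(0.3, 1.0), 200.0, seed=5)
        gaps, stat, p = residual_gof(HawkesModel(1.0, ExponentialKernel(0.3, 1.0)), events, 200.0)
        assert np.all(gaps > 0)
        assert 0.0 <= stat <= 1.0
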