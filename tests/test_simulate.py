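"""Stochastic engines: exactness, mode equivalence, balance, scaling, replay."""

import numpy as np
import pytest

from wccrit.fixtures import master_equation_stationary
from wccrit.linear_noise import build_linear_solution, rate_statistics
from wccrit.model import ModelParams, stable_fixed_point
from wccrit.simulate import (
    NetworkState,
    RateTimeSeries,
    SpikeEventStream,
    gillespie,
    gillespie_occupancy,
    langevin,
    rate_from_counts,
    rate_series_from_events,
    stationary_init,
)


class TestGillespie:
    def test_absorbing_state_no_events(self):
        p = ModelParams.from_balance(0.1, 1.0, h=0.0, n=10)
        stream = gillespie(p, 100.0, 1, record="events", init=NetworkState(0, 0))
        assert len(stream) == 0
        series = gillespie(p, 100.0, 1, dt_sample=1.0, init=NetworkState(0, 0))
        assert np.all(series.rate == 0.0)
        assert len(series) == 100

    def test_reproducible_and_seed_sensitive(self):
        p = ModelParams.from_balance(0.2, 1.0, h=1e-3, n=50)
        a = gillespie(p, 500.0, 7, dt_sample=1.0)
        b = gillespie(p, 500.0, 7, dt_sample=1.0)
        c = gillespie(p, 500.0, 8, dt_sample=1.0)
        assert np.array_equal(a.k, b.k) and np.array_equal(a.rate, b.rate)
        assert not np.array_equal(a.k, c.k)

    def test_series_satisfies_rate_identity(self):
        p = ModelParams.from_balance(0.2, 1.0, h=1e-3, n=50)
        s = gillespie(p, 300.0, 3, dt_sample=0.5)
        assert np.allclose(s.rate, rate_from_counts(s.k, s.l, p))

    def test_events_and_series_paths_agree(self):
        p = ModelParams.from_balance(0.2, 1.0, h=1e-3, n=30)
        stream, series = gillespie(p, 200.0, 5, record="both", dt_sample=1.0)
        k_path, _ = stream.replay()
        assert 0 <= k_path.min() and k_path.max() <= 30
        assert series.spike_counts.sum() == int(np.sum(stream.deltas == 1))

    def test_small_n_stationary_matches_master_equation(self):
        # exactness of the engine against the generator null-space oracle
        p = ModelParams(w_e=0.3, w_i=0.1, h=0.01, n=2)
        pi = master_equation_stationary(p)
        occ = gillespie_occupancy(p, 300_000, 11, init=NetworkState(0, 0))
        tv = 0.5 * np.abs(pi - occ).sum()
        assert tv <= 0.02

    def test_mode_equivalence_aggregated_vs_per_neuron(self):
        # exchangeability: lumped four-channel chain and literal neuron-level
        # algorithm give the same stationary activity within Monte-Carlo error
        p = ModelParams.from_balance(0.2, 0.4, h=1e-2, n=100)
        t_max, t_burn = 4000.0, 500.0
        agg = gillespie(p, t_max, 21, mode="aggregated", dt_sample=1.0, burn_in=t_burn)
        per = gillespie(p, t_max, 22, mode="per_neuron", dt_sample=1.0, burn_in=t_burn)
        sig_a = (agg.k + agg.l) / (2.0 * p.n)
        sig_p = (per.k + per.l) / (2.0 * p.n)

        def batch_se(x, nb=20):
            b = len(x) // nb
            means = x[: nb * b].reshape(nb, b).mean(axis=1)
            return means.std(ddof=1) / np.sqrt(nb)

        joint = np.hypot(batch_se(sig_a), batch_se(sig_p))
        assert abs(sig_a.mean() - sig_p.mean()) <= 3 * joint
        assert np.var(sig_p) == pytest.approx(np.var(sig_a), rel=0.5)

    def test_excitation_inhibition_balance(self):
        # symmetric weights: <Delta> -> 0 as N grows.  The balance is exact
        # only in the large-N limit; at finite N the nonlinear coupling of
        # fluctuations leaves a systematic O(1/N) offset, so the assertion
        # allows 3 SE of statistical error plus a 5/N systematic margin and
        # checks the offset actually shrinks with N.
        means = {}
        for n in (1000, 10_000):
            p = ModelParams.from_balance(1.0, 13.8, h=1e-5, n=n)
            s = gillespie(p, 20_000.0, 31, dt_sample=1.0, burn_in=1000.0)
            delta = (s.k - s.l) / (2.0 * p.n)
            nb = 20
            b = len(delta) // nb
            batch = delta[: nb * b].reshape(nb, b).mean(axis=1)
            se = batch.std(ddof=1) / np.sqrt(nb)
            assert abs(delta.mean()) <= 3 * se + 5.0 / n
            means[n] = abs(delta.mean())
        assert means[10_000] < means[1000]

    def test_mean_activity_converges_to_fixed_point(self):
        # finite-size gap <Sigma> - Sigma0 shrinks monotonically with N.
        # Run in the supercritical linear regime (w0 = 1, where the squared
        # CV is of order 10): closer to threshold small networks spend most
        # of their time in fluctuation-driven down-states, far from the
        # deterministic fixed point, and the gap never closes.
        gaps = []
        for n in (100, 1000, 10_000):
            p = ModelParams.from_balance(1.0, 13.8, h=1e-3, n=n)
            sigma0 = stable_fixed_point(p).sigma0
            s = gillespie(p, 10_000.0, 41, dt_sample=1.0, burn_in=500.0)
            sigma = (s.k + s.l) / (2.0 * p.n)
            gaps.append(abs(sigma.mean() - sigma0))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_variance_scaling_matches_linear_noise(self):
        # N * Var(R) approaches the analytic sigma_RR within 10% at N = 1e4
        # in the linear regime (N >> squared CV)
        p = ModelParams.from_balance(1.0, 13.8, h=1e-5, n=10_000)
        sigma_rr = rate_statistics(build_linear_solution(p)).sigma_rr
        s = gillespie(p, 20_000.0, 51, dt_sample=0.5, burn_in=500.0)
        assert p.n * np.var(s.rate) == pytest.approx(sigma_rr, rel=0.10)

    def test_event_budget_overflow_raises(self):
        p = ModelParams.from_balance(0.2, 1.0, h=1e-2, n=100)
        with pytest.raises(RuntimeError, match="event budget"):
            gillespie(p, 1e5, 1, record="events", max_events=100)


class TestLangevin:
    def test_deterministic_flow_reaches_fixed_point(self):
        p = ModelParams.from_balance(1.0, 13.8, h=1e-5, n=1000)
        sigma0 = stable_fixed_point(p).sigma0
        for k0 in (0, 500, 1000):
            s = langevin(p, 400.0, 0, noise=False, init=NetworkState(k0, k0))
            assert s.k[-1] / p.n == pytest.approx(sigma0, abs=1e-6)
            assert s.l[-1] / p.n == pytest.approx(sigma0, abs=1e-6)

    def test_stationary_variance_near_linear_noise(self):
        p = ModelParams.from_balance(1.0, 13.8, h=1e-5, n=10_000)
        sigma_rr = rate_statistics(build_linear_solution(p)).sigma_rr
        s = langevin(p, 20_000.0, 61, dt=1e-2, dt_sample=0.5, burn_in=500.0)
        assert p.n * np.var(s.rate) == pytest.approx(sigma_rr, rel=0.15)

    def test_bounds_respected(self):
        p = ModelParams.from_balance(1.0, 13.8, h=0.1, n=100)
        s = langevin(p, 2000.0, 71, dt=1e-3)
        assert np.all(s.k >= 0) and np.all(s.k <= p.n)

    def test_coarse_step_warns(self):
        p = ModelParams.from_balance(0.2, 1.0, h=1e-3, n=100)
        with pytest.warns(UserWarning, match="too coarse"):
            langevin(p, 10.0, 1, dt=20.0)


class TestEventReplay:
    def _params(self):
        return ModelParams(w_e=0.0, w_i=0.0, h=0.1, n=5)

    def test_empty_stream_constant_series(self):
        stream = SpikeEventStream(
            initial_state=NetworkState(2, 1), times=np.array([]),
            pops=np.array([], np.int8), deltas=np.array([], np.int8),
            params=self._params(), t_max=10.0,
        )
        series = rate_series_from_events(stream, 1.0)
        assert np.all(series.k == 2) and np.all(series.l == 1)

    def test_single_event_replay_semantics(self):
        stream = SpikeEventStream(
            initial_state=NetworkState(1, 0), times=np.array([5.3]),
            pops=np.array([0], np.int8), deltas=np.array([1], np.int8),
            params=self._params(), t_max=10.0,
        )
        series = rate_series_from_events(stream, 1.0)
        assert np.all(series.k[:6] == 1)  # grid points 0..5 precede the event
        assert np.all(series.k[6:] == 2)

    def test_mean_rate_equals_spike_count_identity(self):
        # activations happen at total rate 2N(1-Sigma)f = 2NR, so the mean
        # reconstructed R must match spikes/(2N T) up to discretization
        p = ModelParams.from_balance(0.2, 0.4, h=1e-2, n=100)
        stream = gillespie(p, 5000.0, 81, record="events")
        series = rate_series_from_events(stream, 0.25)
        n_spikes = int(np.sum(stream.deltas == 1))
        expected = n_spikes / (2.0 * p.n * stream.duration)
        assert series.rate.mean() == pytest.approx(expected, rel=0.02)

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpikeEventStream(
                initial_state=NetworkState(1, 1), times=np.array([2.0, 1.0]),
                pops=np.array([0, 0], np.int8), deltas=np.array([1, 1], np.int8),
                params=self._params(),
            )

    def test_bound_violation_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            SpikeEventStream(
                initial_state=NetworkState(0, 0), times=np.array([1.0]),
                pops=np.array([0], np.int8), deltas=np.array([-1], np.int8),
                params=self._params(),
            )


class TestDefaults:
    def test_stationary_init_rounds_fixed_point(self):
        p = ModelParams.from_balance(0.2, 13.8, h=1e-3, n=1000)
        init = stationary_init(p)
        assert init.k == round(stable_fixed_point(p).sigma0 * p.n)

    def test_invalid_tmax_rejected(self):
        with pytest.raises(ValueError):
            gillespie(ModelParams(), 0.0, 1)
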