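"""Avalanche detection, power-law MLE, size-duration scaling, shape collapse."""

import numpy as np
import pytest

from wccrit.avalanches import (
    AvalancheCatalog,
    avalanche_shape,
    crackling_gamma,
    detect_binned,
    detect_binned_from_counts,
    detect_threshold,
    fit_power_law,
    fit_power_law_sweep,
    size_duration_scaling,
)
from wccrit.fixtures import branching_avalanches, ou_series, powerlaw_samples
from wccrit.model import ModelParams
from wccrit.simulate import NetworkState, RateTimeSeries, SpikeEventStream


def _stream_from_spikes(spike_times, t_max=None):
    """Event stream with E-activations at the given times (k kept small)."""
    times = np.asarray(spike_times, dtype=float)
    n_ev = len(times)
    # interleave deactivations so k stays within bounds
    all_times, pops, deltas = [], [], []
    for t in times:
        all_times += [t, t + 1e-6]
        pops += [0, 0]
        deltas += [1, -1]
    params = ModelParams(w_e=0.0, w_i=0.0, h=0.1, n=4)
    return SpikeEventStream(
        initial_state=NetworkState(0, 0),
        times=np.array(all_times),
        pops=np.array(pops, np.int8),
        deltas=np.array(deltas, np.int8),
        params=params,
        t_max=t_max,
    )


class TestBinnedDetection:
    def test_hand_enumerated_example(self):
        # spikes at 0.1, 0.2, 0.9 ms share bin 0; 2.5 ms is isolated
        stream = _stream_from_spikes([0.1, 0.2, 0.9, 2.5], t_max=4.0)
        cat = detect_binned(stream, 1.0)
        assert list(cat.sizes) == [3, 1]
        assert list(cat.durations) == [1.0, 1.0]

    def test_single_giant_bin(self):
        stream = _stream_from_spikes([0.1, 5.0, 40.0], t_max=50.0)
        cat = detect_binned(stream, 1000.0)
        assert len(cat) == 1
        assert cat.sizes[0] == 3

    def test_empty_stream_empty_catalog(self):
        stream = _stream_from_spikes([], t_max=10.0)
        assert len(detect_binned(stream, 1.0)) == 0

    def test_sizes_partition_all_spikes(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.7, size=2000)
        cat = detect_binned_from_counts(counts, 1.0)
        assert cat.sizes.sum() == counts.sum()

    def test_avalanche_count_nonincreasing_in_delta(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(0.4, size=4096)
        ns = []
        for factor in (1, 2, 4, 8, 16):
            re = counts.reshape(-1, factor).sum(axis=1)
            ns.append(len(detect_binned_from_counts(re, float(factor))))
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_durations_are_bin_multiples(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(0.5, size=1000)
        cat = detect_binned_from_counts(counts, 2.0)
        assert np.allclose(cat.durations % 2.0, 0.0)


class TestThresholdDetection:
    def _series(self, values, dt=1.0):
        return RateTimeSeries(dt=dt, rate=np.asarray(values, dtype=float))

    def test_zero_threshold_defs_2_and_3_coincide(self):
        rng = np.random.default_rng(8)
        r = np.abs(rng.normal(0, 1, 500)) * (rng.random(500) > 0.3)
        s = self._series(r)
        c2 = detect_threshold(s, 0.0, 2)
        c3 = detect_threshold(s, 0.0, 3)
        assert np.allclose(c2.sizes, c3.sizes)
        assert np.allclose(c2.durations, c3.durations)

    def test_constant_series_single_avalanche(self):
        s = self._series(np.full(100, 2.5))
        cat = detect_threshold(s, 1.0, 2)
        assert len(cat) == 1
        assert cat.durations[0] == 100.0

    def test_threshold_above_max_empty(self):
        s = self._series([0.1, 0.2, 0.1])
        assert len(detect_threshold(s, 5.0, 2)) == 0

    def test_size_def1_requires_spike_counts(self):
        s = self._series([0.1, 0.2, 0.1])
        with pytest.raises(ValueError, match="spike counts"):
            detect_threshold(s, 0.05, 1)

    def test_size_def3_subtracts_threshold(self):
        s = self._series([0.0, 2.0, 3.0, 0.0])
        c2 = detect_threshold(s, 1.0, 2)
        c3 = detect_threshold(s, 1.0, 3)
        assert c2.sizes[0] == pytest.approx(5.0)
        assert c3.sizes[0] == pytest.approx(3.0)
        assert c2.durations[0] == 2.0

    def test_ou_null_exponents(self):
        # excursions of an OU signal above its mean: first-passage theory
        # gives duration tail ~ T^-3/2 and size tail ~ S^-4/3 in the
        # window between the sampling step and the correlation time
        ou = ou_series(400.0, 1.0, 1.0, 2 * 10**6, 11)
        cat = detect_threshold(ou, 0.0, 3, spike_units=False)
        dur_fit = fit_power_law(cat.durations, 2.0)
        size_fit = fit_power_law(cat.sizes, float(np.quantile(cat.sizes, 0.5)))
        assert dur_fit.exponent == pytest.approx(1.5, abs=0.1)
        assert size_fit.exponent == pytest.approx(4.0 / 3.0, abs=0.1)


class TestPowerLawFit:
    def test_continuous_closed_form_identity(self):
        x = np.exp([1.0, 2.0, 3.0, 4.0])
        fit = fit_power_law(x, 1.0)
        assert fit.exponent == pytest.approx(1.0 + 4.0 / 10.0, rel=1e-12)

    def test_discrete_recovers_exponent(self):
        s = powerlaw_samples(1.5, 10, 10**5, 42, discrete=True)
        fit = fit_power_law(s, 10, discrete=True)
        assert abs(fit.exponent - 1.5) <= 3 * fit.stderr
        assert fit.stderr == pytest.approx(
            (fit.exponent - 1.0) / np.sqrt(fit.n_tail), rel=1e-9
        )

    def test_continuous_recovers_exponent(self):
        s = powerlaw_samples(2.0, 1.0, 10**5, 43)
        fit = fit_power_law(s, 1.0)
        assert abs(fit.exponent - 2.0) <= 0.01

    def test_low_sample_flagged_not_rejected(self):
        s = powerlaw_samples(2.0, 1.0, 30, 44)
        assert fit_power_law(s, 1.0).low_sample

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law(np.full(100, 3.0), 1.0)
        with pytest.raises(ValueError, match="tail samples"):
            fit_power_law(np.array([1.0]), 1.0)

    def test_xmin_sweep_shapes(self):
        s = powerlaw_samples(1.8, 1.0, 10**4, 45)
        fits = fit_power_law_sweep(s, [1.0, 2.0, 4.0])
        assert [f.xmin for f in fits] == [1.0, 2.0, 4.0]
        assert all(abs(f.exponent - 1.8) < 0.1 for f in fits)

    def test_ks_small_for_true_power_law(self):
        s = powerlaw_samples(2.5, 1.0, 10**4, 46)
        fit = fit_power_law(s, 1.0)
        assert fit.ks < 1.63 / np.sqrt(fit.n_tail)  # 1% KS band

    def test_calibration_bias_and_coverage(self):
        # 100 replicates at n = 1e4: mean estimate within 0.01 of truth,
        # nominal 2-sigma coverage at least 90%
        est, cover = [], 0
        for rep in range(100):
            s = powerlaw_samples(1.5, 1.0, 10**4, 1000 + rep)
            f = fit_power_law(s, 1.0)
            est.append(f.exponent)
            cover += abs(f.exponent - 1.5) <= 2 * f.stderr
        assert abs(np.mean(est) - 1.5) <= 0.01
        assert cover >= 90


class TestSizeDurationScaling:
    def test_crackling_prediction(self):
        assert crackling_gamma(1.5, 2.0) == pytest.approx(2.0)

    def test_exact_quadratic_catalog(self):
        t = np.arange(1.0, 50.0)
        cat = AvalancheCatalog(sizes=t**2, durations=t, method="binned", delta=1.0)
        fit = size_duration_scaling(cat, (1.0, 49.0))
        assert fit.gamma == pytest.approx(2.0, rel=1e-10)

    def test_window_filtering_and_errors(self):
        t = np.arange(1.0, 20.0)
        cat = AvalancheCatalog(sizes=t**1.7, durations=t, method="binned", delta=1.0)
        with pytest.raises(ValueError, match="fit window"):
            size_duration_scaling(cat, (100.0, 200.0))
        fit = size_duration_scaling(cat, (5.0, 15.0))
        assert fit.gamma == pytest.approx(1.7, rel=1e-9)

    def test_branching_catalog_scaling_near_two(self):
        cat = branching_avalanches(1.0, 10**5, 9)
        fit = size_duration_scaling(cat, (10.0, 100.0))
        assert fit.gamma == pytest.approx(2.0, abs=0.25)


class TestShapeCollapse:
    def _uniform_catalog(self):
        profiles = [np.array([1, 2, 1])] * 30 + [np.array([2, 4, 4, 2])] * 30
        sizes = np.array([4] * 30 + [12] * 30)
        durations = np.array([3.0] * 30 + [4.0] * 30)
        return AvalancheCatalog(
            sizes=sizes, durations=durations, method="binned", delta=1.0,
            profiles=profiles,
        )

    def test_identical_avalanches_collapse_perfectly(self):
        profiles = [np.array([1, 3, 1])] * 40
        cat = AvalancheCatalog(
            sizes=np.full(40, 5), durations=np.full(40, 3.0), method="binned",
            delta=1.0, profiles=profiles,
        )
        res = avalanche_shape(cat, [3.0], 2.0)
        assert res.quality == pytest.approx(0.0, abs=1e-15)

    def test_small_classes_skipped(self):
        cat = self._uniform_catalog()
        res = avalanche_shape(cat, [3.0, 4.0, 17.0], 2.0, min_count=20)
        assert 17.0 in res.skipped
        assert set(res.durations) == {3.0, 4.0}

    def test_critical_collapses_better_than_subcritical(self):
        durs = [6.0, 10.0, 16.0]
        crit = branching_avalanches(1.0, 3 * 10**4, 12, keep_profiles=True)
        off = branching_avalanches(0.8, 3 * 10**4, 12, keep_profiles=True)
        q_crit = avalanche_shape(crit, durs, 2.0).quality
        q_off = avalanche_shape(off, durs, 2.0).quality
        assert q_crit < q_off

    def test_profiles_required(self):
        cat = AvalancheCatalog(
            sizes=np.array([2.0]), durations=np.array([1.0]), method="threshold",
        )
        with pytest.raises(ValueError, match="profiles"):
            avalanche_shape(cat, [1.0], 2.0)
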