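"""Numba kernels for the stochastic engines.

The aggregated Gillespie kernel exploits exchangeability of the
identical all-to-all neurons: (k, l) is a lumped continuous-time Markov
chain with four reaction channels

    E-deactivation  rate alpha*k        (k -> k-1)
    E-activation    rate (N-k)*f(s)     (k -> k+1)
    I-deactivation  rate alpha*l        (l -> l-1)
    I-activation    rate (N-l)*f(s)     (l -> l+1)

with s = (w_E*k - w_I*l)/N + h.  Each kernel seeds numba's internal
np.random state, so trajectories are reproducible given the seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _f(s, beta):
    if s > 0.0:
        return beta * math.tanh(s)
    return 0.0


@njit(cache=True)
def gillespie_series_kernel(
    n, alpha, beta, w_e, w_i, h, k0, l0, n_samples, dt_sample, seed
):
    """Aggregated Gillespie run sampled on a uniform grid.

    Returns (k_samples, l_samples, spike_counts) where the sample at
    grid time i*dt_sample is the state immediately after the last event
    at or before that time, and spike_counts[i] is the number of
    activation events (either population) in [i*dt_sample, (i+1)*dt_sample).
    """
    np.random.seed(seed)
    ks = np.empty(n_samples, np.int64)
    ls = np.empty(n_samples, np.int64)
    spikes = np.zeros(n_samples, np.int64)
    k = k0
    l = l0
    t = 0.0
    t_end = n_samples * dt_sample
    idx = 0
    while True:
        s = (w_e * k - w_i * l) / n + h
        f = _f(s, beta)
        r_ed = alpha * k
        r_ea = (n - k) * f
        r_id = alpha * l
        r_ia = (n - l) * f
        r = r_ed + r_ea + r_id + r_ia
        if r <= 0.0:
            # absorbing state (h = 0, k = l = 0): idle until t_end
            while idx < n_samples:
                ks[idx] = k
                ls[idx] = l
                idx += 1
            break
        t_next = t + np.random.exponential(1.0 / r)
        while idx < n_samples and idx * dt_sample < t_next:
            ks[idx] = k
            ls[idx] = l
            idx += 1
        if t_next >= t_end:
            break
        u = np.random.random() * r
        if u < r_ed:
            k -= 1
        elif u < r_ed + r_ea:
            k += 1
            spikes[int(t_next / dt_sample)] += 1
        elif u < r_ed + r_ea + r_id:
            l -= 1
        else:
            l += 1
            spikes[int(t_next / dt_sample)] += 1
        t = t_next
    return ks, ls, spikes


@njit(cache=True)
def gillespie_events_kernel(
    n, alpha, beta, w_e, w_i, h, k0, l0, t_max, max_events, seed
):
    """Aggregated Gillespie run recording every event.

    Returns (times, pop, delta, n_events, t_final); pop is 0 for E and
    1 for I, delta is +1 (activation) or -1 (deactivation).  Stops at
    t_max or when max_events is reached, whichever comes first.
    """
    np.random.seed(seed)
    times = np.empty(max_events, np.float64)
    pops = np.empty(max_events, np.int8)
    deltas = np.empty(max_events, np.int8)
    k = k0
    l = l0
    t = 0.0
    m = 0
    while m < max_events:
        s = (w_e * k - w_i * l) / n + h
        f = _f(s, beta)
        r_ed = alpha * k
        r_ea = (n - k) * f
        r_id = alpha * l
        r_ia = (n - l) * f
        r = r_ed + r_ea + r_id + r_ia
        if r <= 0.0:
            t = t_max
            break
        t_next = t + np.random.exponential(1.0 / r)
        if t_next >= t_max:
            t = t_max
            break
        u = np.random.random() * r
        if u < r_ed:
            k -= 1
            pops[m] = 0
            deltas[m] = -1
        elif u < r_ed + r_ea:
            k += 1
            pops[m] = 0
            deltas[m] = 1
        elif u < r_ed + r_ea + r_id:
            l -= 1
            pops[m] = 1
            deltas[m] = -1
        else:
            l += 1
            pops[m] = 1
            deltas[m] = 1
        times[m] = t_next
        t = t_next
        m += 1
    return times[:m], pops[:m], deltas[:m], m, t


@njit(cache=True)
def gillespie_occupancy_kernel(n, alpha, beta, w_e, w_i, h, k0, l0, n_events, seed):
    """Time-weighted occupancy over (k, l) states from n_events jumps.

    Returns the (N+1)x(N+1) matrix of total residence times, the
    empirical stationary distribution of the chain after normalization.
    """
    np.random.seed(seed)
    occ = np.zeros((n + 1, n + 1), np.float64)
    k = k0
    l = l0
    for _ in range(n_events):
        s = (w_e * k - w_i * l) / n + h
        f = _f(s, beta)
        r_ed = alpha * k
        r_ea = (n - k) * f
        r_id = alpha * l
        r_ia = (n - l) * f
        r = r_ed + r_ea + r_id + r_ia
        if r <= 0.0:
            occ[k, l] = 1.0
            break
        occ[k, l] += np.random.exponential(1.0 / r)
        u = np.random.random() * r
        if u < r_ed:
            k -= 1
        elif u < r_ed + r_ea:
            k += 1
        elif u < r_ed + r_ea + r_id:
            l -= 1
        else:
            l += 1
    return occ


@njit(cache=True)
def langevin_series_kernel(
    n, alpha, beta, w_e, w_i, h, k0, l0, dt, n_steps, sample_every, noise_on, seed
):
    """Euler-Maruyama integration of the nonlinear Langevin equations.

    dk = [-alpha*k + f(s)(N-k)] dt + sqrt(alpha*k + f(s)(N-k)) dW_E,
    and likewise for l.  The noise-amplitude argument is clamped below
    at 0 before the square root and (k, l) are clamped to [0, N] after
    each step.  Samples every sample_every steps (including the initial
    state).
    """
    np.random.seed(seed)
    n_samples = n_steps // sample_every + 1
    ks = np.empty(n_samples, np.float64)
    ls = np.empty(n_samples, np.float64)
    k = k0
    l = l0
    ks[0] = k
    ls[0] = l
    sq = math.sqrt(dt)
    idx = 1
    for step in range(1, n_steps + 1):
        s = (w_e * k - w_i * l) / n + h
        f = _f(s, beta)
        ak = alpha * k + f * (n - k)
        al = alpha * l + f * (n - l)
        dk = (-alpha * k + f * (n - k)) * dt
        dl = (-alpha * l + f * (n - l)) * dt
        if noise_on:
            dk += math.sqrt(max(ak, 0.0)) * sq * np.random.normal(0.0, 1.0)
            dl += math.sqrt(max(al, 0.0)) * sq * np.random.normal(0.0, 1.0)
        k = min(max(k + dk, 0.0), float(n))
        l = min(max(l + dl, 0.0), float(n))
        if step % sample_every == 0:
            ks[idx] = k
            ls[idx] = l
            idx += 1
    return ks[:idx], ls[:idx]
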