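"""Stochastic engines: exact Gillespie simulation and Langevin integration.

The model is a continuous-time Markov chain on the joint state of 2N
two-state neurons.  Because all neurons of a population are exchangeable
(all-to-all coupling, identical weights), the pair (k, l) of active
counts is itself a Markov chain with four reaction channels; the
``aggregated`` engine simulates that lumped chain exactly in O(1) per
event and is the default.  The ``per_neuron`` engine follows the
neuron-level algorithm literally (per-neuron rates, waiting time from
the total rate, neuron chosen proportionally to its rate) and is kept
for fidelity tests; the two produce statistically identical summaries.

The Langevin engine integrates the chemical-Langevin form of the same
dynamics by Euler-Maruyama with square-root multiplicative noise,
default time step dt = 1e-3 ms; it is the efficient route to very large
N, where it agrees with the exact simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import ModelParams, activation, stable_fixed_point

__all__ = [
    "NetworkState",
    "SpikeEventStream",
    "RateTimeSeries",
    "gillespie",
    "langevin",
    "rate_series_from_events",
    "stationary_init",
    "default_burn_in",
]


def _mask_seed(seed: int) -> int:
    return int(seed) % (2**31)


@dataclass(frozen=True)
class NetworkState:
    """Instantaneous lumped network state."""

    k: int  # active excitatory neurons, 0..N
    l: int  # active inhibitory neurons, 0..N
    t: float = 0.0  # ms

    def validate(self, n: int) -> None:
        if not (0 <= self.k <= n and 0 <= self.l <= n):
            raise ValueError(f"state ({self.k}, {self.l}) outside [0, {n}]^2")
        if self.t < 0:
            raise ValueError("time must be >= 0")


@dataclass
class SpikeEventStream:
    """Time-ordered state-change events of a simulation run.

    ``pops`` holds 0 for excitatory, 1 for inhibitory; ``deltas`` is +1
    for an activation (a spike) and -1 for a deactivation.  Replaying
    the events from ``initial_state`` must never leave [0, N]^2.
    """

    initial_state: NetworkState
    times: np.ndarray  # ms, strictly increasing
    pops: np.ndarray  # int8, 0 = E, 1 = I
    deltas: np.ndarray  # int8, +1 or -1
    params: ModelParams
    seed: int | None = None
    t_max: float | None = None  # recording horizon, ms

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pops = np.asarray(self.pops, dtype=np.int8)
        self.deltas = np.asarray(self.deltas, dtype=np.int8)
        if not (len(self.times) == len(self.pops) == len(self.deltas)):
            raise ValueError("times, pops, deltas must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        self.initial_state.validate(self.params.n)
        k, l = self.replay()
        n = self.params.n
        if len(k) and (k.min() < 0 or k.max() > n or l.min() < 0 or l.max() > n):
            raise ValueError("corrupt stream: replay violates state bounds")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def spike_times(self) -> np.ndarray:
        """Times of activation events (both populations pooled)."""
        return self.times[self.deltas == 1]

    def replay(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, l) immediately after each event."""
        dk = np.where(self.pops == 0, self.deltas, 0).astype(np.int64)
        dl = np.where(self.pops == 1, self.deltas, 0).astype(np.int64)
        return (
            self.initial_state.k + np.cumsum(dk),
            self.initial_state.l + np.cumsum(dl),
        )

    @property
    def duration(self) -> float:
        if self.t_max is not None:
            return self.t_max
        return float(self.times[-1]) if len(self.times) else 0.0


@dataclass
class RateTimeSeries:
    """Uniformly sampled firing-rate trajectory.

    ``rate`` is R in ms^-1 on the grid ``t0 + i*dt``.  When the series
    comes from a simulation, the active counts ``k``, ``l`` and the
    per-bin activation counts ``spike_counts`` are carried along; the
    rate then satisfies R = (1 - (k+l)/2N) f((w_E k - w_I l)/N + h)
    sample by sample.
    """

    dt: float  # sampling interval, ms
    rate: np.ndarray  # ms^-1
    t0: float = 0.0
    k: np.ndarray | None = None
    l: np.ndarray | None = None
    spike_counts: np.ndarray | None = None
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.rate = np.asarray(self.rate, dtype=float)

    def __len__(self) -> int:
        return len(self.rate)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.rate))

    @property
    def duration(self) -> float:
        return self.dt * len(self.rate)

    def discard(self, burn_in: float) -> "RateTimeSeries":
        """Drop the first ``burn_in`` ms (for stationary statistics)."""
        i = int(math.ceil(burn_in / self.dt))
        return RateTimeSeries(
            dt=self.dt,
            rate=self.rate[i:],
            t0=self.t0 + i * self.dt,
            k=None if self.k is None else self.k[i:],
            l=None if self.l is None else self.l[i:],
            spike_counts=None if self.spike_counts is None else self.spike_counts[i:],
            params=self.params,
        )


def rate_from_counts(k, l, params: ModelParams) -> np.ndarray:
    """Instantaneous rate R = (1 - (k+l)/2N) f(s), s = (w_E k - w_I l)/N + h."""
    k = np.asarray(k, dtype=float)
    l = np.asarray(l, dtype=float)
    n = params.n
    s = (params.w_e * k - params.w_i * l) / n + params.h
    return (1.0 - (k + l) / (2.0 * n)) * activation(s, params)


def stationary_init(params: ModelParams) -> NetworkState:
    """Default initial condition (k, l) = round(N * Sigma0)."""
    fp = stable_fixed_point(params)
    k0 = int(round(params.n * fp.sigma0))
    return NetworkState(k=k0, l=k0)


def default_burn_in(params: ModelParams) -> float:
    """Burn-in of 20 * max(tau1, tau2) ms tied to the model time scales."""
    fp = stable_fixed_point(params)
    taus = [t for t in (fp.tau1, fp.tau2) if t > 0 and math.isfinite(t)]
    return 20.0 * max(taus) if taus else 0.0


def _resolve_init(params: ModelParams, init: NetworkState | None) -> NetworkState:
    if init is None:
        return stationary_init(params)
    init.validate(params.n)
    return init


def gillespie(
    params: ModelParams,
    t_max: float,
    seed: int,
    *,
    mode: str = "aggregated",
    record: str = "series",
    dt_sample: float = 1.0,
    init: NetworkState | None = None,
    burn_in: float = 0.0,
    max_events: int = 20_000_000,
):
    """Exact stochastic simulation of the lumped Markov chain.

    Parameters
    ----------
    t_max : float
        Recording horizon in ms (after ``burn_in``).
    mode : {"aggregated", "per_neuron"}
        Lumped four-channel chain (default, O(1)/event) or the literal
        neuron-level algorithm.
    record : {"series", "events", "both"}
        What to return: a :class:`RateTimeSeries` sampled every
        ``dt_sample`` ms (with per-bin spike counts), the
        :class:`SpikeEventStream`, or a ``(stream, series)`` pair.
    burn_in : float
        Extra ms simulated and discarded before recording starts
        (series mode only; event recording always starts at t = 0).

    With h = 0 the state (0, 0) is absorbing: the simulation then
    legitimately idles until t_max (constant series, no events).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if mode not in ("aggregated", "per_neuron"):
        raise ValueError(f"unknown mode {mode!r}")
    if record not in ("series", "events", "both"):
        raise ValueError(f"unknown record {record!r}")
    state0 = _resolve_init(params, init)
    seed = _mask_seed(seed)

    if record == "series" and mode == "aggregated":
        n_burn = int(round(burn_in / dt_sample))
        n_samples = n_burn + int(round(t_max / dt_sample))
        ks, ls, spikes = _kernels.gillespie_series_kernel(
            params.n, params.alpha, params.beta, params.w_e, params.w_i,
            params.h, state0.k, state0.l, n_samples, dt_sample, seed,
        )
        series = RateTimeSeries(
            dt=dt_sample,
            rate=rate_from_counts(ks, ls, params),
            k=ks, l=ls, spike_counts=spikes, params=params,
        )
        return series.discard(n_burn * dt_sample) if n_burn else series

    # event-recording paths (and per-neuron mode)
    horizon = burn_in + t_max
    if mode == "aggregated":
        times, pops, deltas, m, t_final = _kernels.gillespie_events_kernel(
            params.n, params.alpha, params.beta, params.w_e, params.w_i,
            params.h, state0.k, state0.l, horizon, max_events, seed,
        )
        if m >= max_events and t_final < horizon:
            raise RuntimeError(
                f"event budget {max_events} exhausted at t = {t_final:.1f} ms; "
                "use record='series' or raise max_events"
            )
    else:
        times, pops, deltas = _per_neuron_events(params, horizon, state0, seed)

    stream = SpikeEventStream(
        initial_state=state0, times=times, pops=pops, deltas=deltas,
        params=params, seed=seed, t_max=horizon,
    )
    if record == "events":
        return stream
    series = rate_series_from_events(stream, dt_sample).discard(burn_in)
    if record == "series":
        return series
    return stream, series


def _per_neuron_events(params, t_max, state0, seed):
    """Literal neuron-level Gillespie: per-neuron rates, total-rate waiting
    time, neuron chosen with probability r_i / r."""
    rng = np.random.default_rng(seed)
    n = params.n
    active = np.zeros(2 * n, dtype=bool)  # first n excitatory, next n inhibitory
    active[:state0.k] = True
    active[n:n + state0.l] = True
    times, pops, deltas = [], [], []
    t = 0.0
    while True:
        k = int(active[:n].sum())
        l = int(active[n:].sum())
        s = (params.w_e * k - params.w_i * l) / n + params.h
        f = activation(s, params)
        rates = np.where(active, params.alpha, f)  # r_i per neuron
        r = rates.sum()
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= t_max:
            break
        i = int(np.searchsorted(np.cumsum(rates), rng.random() * r))
        delta = -1 if active[i] else 1
        active[i] = not active[i]
        times.append(t)
        pops.append(0 if i < n else 1)
        deltas.append(delta)
    return (
        np.array(times, dtype=float),
        np.array(pops, dtype=np.int8),
        np.array(deltas, dtype=np.int8),
    )


def gillespie_occupancy(
    params: ModelParams,
    n_events: int,
    seed: int,
    *,
    init: NetworkState | None = None,
) -> np.ndarray:
    """Empirical stationary distribution over (k, l) from residence times.

    Runs the aggregated engine for ``n_events`` jumps and returns the
    normalized (N+1)x(N+1) matrix of time spent in each state; the
    natural object to compare against the master-equation oracle.
    """
    state0 = _resolve_init(params, init)
    occ = _kernels.gillespie_occupancy_kernel(
        params.n, params.alpha, params.beta, params.w_e, params.w_i,
        params.h, state0.k, state0.l, int(n_events), _mask_seed(seed),
    )
    total = occ.sum()
    if total <= 0:
        raise RuntimeError("no residence time accumulated")
    return occ / total


def langevin(
    params: ModelParams,
    t_max: float,
    seed: int,
    *,
    dt: float = 1e-3,
    dt_sample: float = 1.0,
    init: NetworkState | None = None,
    burn_in: float = 0.0,
    noise: bool = True,
) -> RateTimeSeries:
    """Euler-Maruyama integration of the nonlinear Langevin equations.

    Continuous (k, l) with drift -alpha*k + f(s)(N-k) and noise
    amplitude sqrt(alpha*k + f(s)(N-k)) (clamped at 0 under the root);
    (k, l) clamped to [0, N] after each step.  ``noise=False`` gives the
    deterministic mean-field flow (test hook).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= 1.0 / params.alpha:
        warnings.warn(
            f"dt = {dt} ms >= 1/alpha = {1.0 / params.alpha} ms: "
            "Euler-Maruyama step too coarse for stability",
            stacklevel=2,
        )
    state0 = _resolve_init(params, init)
    sample_every = max(int(round(dt_sample / dt)), 1)
    n_steps = int(round((burn_in + t_max) / dt))
    ks, ls = _kernels.langevin_series_kernel(
        params.n, params.alpha, params.beta, params.w_e, params.w_i,
        params.h, float(state0.k), float(state0.l), dt, n_steps,
        sample_every, noise, _mask_seed(seed),
    )
    series = RateTimeSeries(
        dt=sample_every * dt,
        rate=rate_from_counts(ks, ls, params),
        k=ks, l=ls, params=params,
    )
    return series.discard(burn_in) if burn_in else series


def rate_series_from_events(stream: SpikeEventStream, dt_sample: float) -> RateTimeSeries:
    """Sample a rate series from an event stream on a uniform grid.

    The value at grid time t is the state immediately after the last
    event at or before t; per-bin activation counts are included so the
    series supports spike-count (definition 1) avalanche sizes.
    """
    if dt_sample <= 0:
        raise ValueError("dt_sample must be positive")
    horizon = stream.duration
    n_samples = max(int(round(horizon / dt_sample)), 1)
    grid = dt_sample * np.arange(n_samples)
    k_path, l_path = stream.replay()
    idx = np.searchsorted(stream.times, grid, side="right")
    k0, l0 = stream.initial_state.k, stream.initial_state.l
    ks = np.where(idx > 0, k_path[np.maximum(idx - 1, 0)], k0) if len(stream) else np.full(n_samples, k0)
    ls = np.where(idx > 0, l_path[np.maximum(idx - 1, 0)], l0) if len(stream) else np.full(n_samples, l0)
    spike_t = stream.spike_times
    counts, _ = np.histogram(spike_t, bins=n_samples, range=(0.0, n_samples * dt_sample))
    return RateTimeSeries(
        dt=dt_sample,
        rate=rate_from_counts(ks, ls, params=stream.params),
        k=np.asarray(ks, dtype=np.int64),
        l=np.asarray(ls, dtype=np.int64),
        spike_counts=counts.astype(np.int64),
        params=stream.params,
    )
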