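"""Ground-truth generators and brute-force oracles.

Every estimator and the simulation engines are validated against data
with known answers, independent of the Wilson-Cowan model itself:

* a critical Galton-Watson branching process, whose avalanche size and
  duration tails have the mean-field exponents tau_S = 3/2, tau_T = 2;
* an exactly discretized Ornstein-Uhlenbeck process with a known
  autocorrelation time, the null model for threshold-crossing
  avalanches;
* i.i.d. discrete and continuous power-law samples with a known
  exponent, for calibrating the maximum-likelihood estimator;
* the exact stationary distribution of the lumped (k, l) Markov chain
  at tiny N, from a null-space solve of the master-equation generator.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import null_space
from scipy.special import zeta

from .avalanches import AvalancheCatalog
from .model import ModelParams, activation
from .simulate import RateTimeSeries

__all__ = [
    "branching_avalanches",
    "ou_series",
    "powerlaw_samples",
    "master_equation_stationary",
]


def branching_avalanches(
    m: float,
    n_avalanches: int,
    seed: int,
    *,
    max_generations: int = 10**5,
    keep_profiles: bool = False,
) -> AvalancheCatalog:
    """Galton-Watson avalanches with Poisson(m) offspring, one ancestor.

    Size is the total number of individuals, duration the number of
    generations.  At the critical branching ratio m = 1 the tails follow
    P(S) ~ S^(-3/2) and P(T) ~ T^(-2).  The sum of Poisson(m) offspring
    over a generation of z individuals is Poisson(m*z), so each
    generation costs a single draw.  Lineages still alive after
    ``max_generations`` generations are truncated there (a vanishing
    fraction at the sample sizes used).
    """
    if not 0.0 < m <= 1.2:
        raise ValueError("branching ratio m must be in (0, 1.2]")
    if n_avalanches < 1:
        raise ValueError("n_avalanches must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_avalanches, dtype=np.int64)
    durations = np.empty(n_avalanches, dtype=np.int64)
    profiles = [] if keep_profiles else None
    for i in range(n_avalanches):
        z = 1
        size = 1
        gens = [1] if keep_profiles else None
        t = 1
        while z > 0 and t < max_generations:
            z = int(rng.poisson(m * z))
            if z > 0:
                size += z
                t += 1
                if keep_profiles:
                    gens.append(z)
        sizes[i] = size
        durations[i] = t
        if keep_profiles:
            profiles.append(np.array(gens, dtype=np.int64))
    return AvalancheCatalog(
        sizes=sizes,
        durations=durations.astype(float),
        method="branching",
        delta=1.0,
        profiles=profiles,
        meta={"m": m, "seed": seed},
    )


def ou_series(
    tau: float,
    sigma: float,
    dt: float,
    n: int,
    seed: int,
    *,
    mean: float = 0.0,
) -> RateTimeSeries:
    """Stationary Ornstein-Uhlenbeck series by exact discretization.

    x_{t+dt} = mean + rho (x_t - mean) + sigma sqrt(1 - rho^2) z with
    rho = exp(-dt/tau), started from the stationary law, so the sample
    autocorrelation is exactly exp(-lag/tau) in expectation at every lag.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0 < dt < tau:
        raise ValueError("need 0 < dt < tau")
    rng = np.random.default_rng(seed)
    rho = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = mean + sigma * rng.standard_normal()
    innov = sigma * np.sqrt(1.0 - rho**2) * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + rho * (x[i - 1] - mean) + innov[i - 1]
    return RateTimeSeries(dt=dt, rate=x)


def powerlaw_samples(
    tau: float,
    xmin: float,
    n: int,
    seed: int,
    *,
    discrete: bool = False,
) -> np.ndarray:
    """i.i.d. samples from P(x) ~ x^(-tau), x >= xmin.

    Continuous: exact inverse-CDF, x = xmin * u^(-1/(tau-1)).  Discrete:
    exact CDF inversion against the zeta-normalized law by vectorized
    doubling-and-bisection search (no rounding approximation).
    """
    if tau <= 1.0:
        raise ValueError("tau must be > 1 for a normalizable power law")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    if not discrete:
        return xmin * (1.0 - u) ** (-1.0 / (tau - 1.0))

    xmin_i = int(round(xmin))
    if xmin_i < 1:
        raise ValueError("discrete law needs xmin >= 1")
    z0 = zeta(tau, xmin_i)
    # P(X > x) = zeta(tau, x+1) / zeta(tau, xmin); find the smallest x
    # with P(X <= x) >= u, i.e. sf(x) <= 1 - u
    target = (1.0 - u) * z0  # compare with zeta(tau, x+1)
    hi = np.full(n, xmin_i, dtype=np.int64)
    while True:
        mask = zeta(tau, hi + 1) > target
        if not mask.any():
            break
        hi[mask] *= 2
    lo = np.maximum(hi // 2, xmin_i)
    while np.any(hi > lo):
        mid = (lo + hi) // 2
        go_up = zeta(tau, mid + 1) > target
        lo = np.where(go_up, mid + 1, lo)
        hi = np.where(go_up, hi, mid)
    return hi


def _generator_matrix(params: ModelParams) -> np.ndarray:
    """Dense generator Q of the lumped (k, l) chain, state index k*(N+1)+l."""
    n = params.n
    dim = (n + 1) ** 2
    q = np.zeros((dim, dim))
    for k in range(n + 1):
        for l in range(n + 1):
            i = k * (n + 1) + l
            s = (params.w_e * k - params.w_i * l) / n + params.h
            f = activation(s, params)
            moves = []
            if k > 0:
                moves.append(((k - 1) * (n + 1) + l, params.alpha * k))
            if k < n:
                moves.append(((k + 1) * (n + 1) + l, (n - k) * f))
            if l > 0:
                moves.append((k * (n + 1) + l - 1, params.alpha * l))
            if l < n:
                moves.append((k * (n + 1) + l + 1, (n - l) * f))
            for j, rate in moves:
                q[i, j] = rate
                q[i, i] -= rate
    return q


def master_equation_stationary(params: ModelParams) -> np.ndarray:
    """Exact stationary distribution pi(k, l) of the lumped chain, N <= 6.

    Builds the (N+1)^2-state generator with channel rates {alpha*k,
    (N-k) f(s), alpha*l, (N-l) f(s)} and solves pi Q = 0 by null-space
    computation.  For h = 0 the chain is reducible (absorbing state at
    the origin): the point mass at (0, 0) is returned with a warning.
    """
    n = params.n
    if n > 6:
        raise ValueError("master-equation oracle capped at N <= 6")
    pi = np.zeros((n + 1, n + 1))
    if params.h == 0.0:
        warnings.warn(
            "h = 0: chain is reducible, returning the absorbing point mass",
            stacklevel=2,
        )
        pi[0, 0] = 1.0
        return pi
    q = _generator_matrix(params)
    ns = null_space(q.T)
    if ns.shape[1] != 1:
        raise RuntimeError(f"expected a unique stationary vector, got {ns.shape[1]}")
    v = ns[:, 0]
    v = np.abs(v) / np.abs(v).sum()
    return v.reshape(n + 1, n + 1)
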