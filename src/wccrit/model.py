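"""Deterministic layer of the stochastic Wilson-Cowan model.

Two homogeneous populations of ``N`` excitatory and ``N`` inhibitory
two-state (active/quiescent) neurons, all-to-all coupled with symmetric
weights.  Active neurons deactivate at rate ``alpha``; quiescent neurons
activate at rate ``f(s)``, a saturating function of the synaptic input
``s``.  In the large-``N`` limit the mean activity ``Sigma = (k+l)/2N``
obeys

    dSigma/dt = -alpha*Sigma + (1 - Sigma)*f(w0*Sigma + h),

with net coupling ``w0 = w_E - w_I`` acting as the control parameter.
For ``h = 0`` the quiescent state ``Sigma0 = 0`` loses stability at the
critical coupling ``w0c = alpha/beta``, where the fixed-point firing rate
``R0 = (1 - Sigma0) f(s0)`` vanishes continuously: a second-order-like
transition with ``R0`` as the order parameter.

All rates are in ms^-1 internally; Hz only at reporting boundaries
(multiply by 1000).  Synaptic inputs and weights are dimensionless (the
membrane-potential scale is absorbed into the units of ``s``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "FixedPoint",
    "activation",
    "activation_deriv",
    "solve_fixed_points",
    "stable_fixed_point",
    "relaxation_times",
    "jacobian_relaxation_times",
    "critical_coupling",
    "fixed_point_rate",
    "MS_TO_HZ",
]

#: conversion factor from ms^-1 to Hz
MS_TO_HZ = 1000.0


@dataclass(frozen=True)
class ModelParams:
    """Model constants; the single source of truth for units.

    Parameters
    ----------
    alpha : float
        Deactivation rate (ms^-1).
    beta : float
        Activation rate scale (ms^-1).
    w_e, w_i : float
        Excitatory / inhibitory synaptic weights (dimensionless).
    h : float
        External input (dimensionless).
    n : int
        Neurons per population (N_E = N_I = N).
    """

    alpha: float = 0.1
    beta: float = 1.0
    w_e: float = 6.95
    w_i: float = 6.85
    h: float = 0.0
    n: int = 10**5

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive rates (ms^-1)")
        if self.n < 1:
            raise ValueError("n (neurons per population) must be >= 1")
        if self.h < 0:
            raise ValueError("external input h must be >= 0")
        if self.w_e < 0 or self.w_i < 0:
            raise ValueError("weights w_e, w_i must be >= 0")

    @property
    def w0(self) -> float:
        """Net coupling w_E - w_I (the control parameter)."""
        return self.w_e - self.w_i

    @property
    def w_sum(self) -> float:
        """Total coupling w_E + w_I (sets the feed-forward term)."""
        return self.w_e + self.w_i

    @classmethod
    def from_balance(
        cls,
        w0: float,
        w_sum: float = 13.8,
        *,
        alpha: float = 0.1,
        beta: float = 1.0,
        h: float = 0.0,
        n: int = 10**5,
    ) -> "ModelParams":
        """Build parameters from (w0, w_sum); exact inverse of (w0, w_sum)."""
        return cls(
            alpha=alpha,
            beta=beta,
            w_e=(w_sum + w0) / 2.0,
            w_i=(w_sum - w0) / 2.0,
            h=h,
            n=n,
        )


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of the mean-activity dynamics with its linear stability.

    ``tau1`` is the slow eigen-time of the Jacobian (negative when the
    point is repulsive -- returned as-is, never clamped), ``tau2`` the
    fast one (always positive).  ``r0 = (1 - sigma0) f(s0)`` is the
    firing rate, the order parameter of the transition.
    """

    sigma0: float
    s0: float
    r0: float
    tau1: float
    tau2: float
    stable: bool

    @property
    def r0_hz(self) -> float:
        return self.r0 * MS_TO_HZ


def activation(s, params: ModelParams):
    """Activation rate f(s) = beta*tanh(s) for s > 0, else 0 (ms^-1).

    Accepts scalars or arrays; raises on non-finite input.
    """
    s_arr = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s_arr)):
        raise ValueError("synaptic input s must be finite")
    out = np.where(s_arr > 0.0, params.beta * np.tanh(s_arr), 0.0)
    if np.isscalar(s) or s_arr.ndim == 0:
        return float(out)
    return out


def activation_deriv(s, params: ModelParams):
    """df/ds, with the right-derivative convention f'(0) = beta.

    The convention matters only at the quiescent fixed point s0 = 0,
    where the dynamics is driven by positive perturbations of s.
    """
    s_arr = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s_arr)):
        raise ValueError("synaptic input s must be finite")
    out = np.where(s_arr >= 0.0, params.beta * (1.0 - np.tanh(s_arr) ** 2), 0.0)
    if np.isscalar(s) or s_arr.ndim == 0:
        return float(out)
    return out


def _fp_residual(sigma: float, params: ModelParams) -> float:
    s = params.w0 * sigma + params.h
    return (1.0 - sigma) * activation(s, params) - params.alpha * sigma


def relaxation_times(params: ModelParams, sigma0: float) -> tuple[float, float]:
    """Eigen-times (tau1, tau2) in ms of the linearized mean dynamics.

    Exact closed forms valid at fixed points of the mean dynamics:

        1/tau1 = (1-Sigma0)^-1 [alpha - beta*w0*(1-Sigma0)^2
                                + alpha^2 Sigma0^2 w0 / beta]
        1/tau2 = alpha / (1-Sigma0)

    A negative tau1 signals a repulsive fixed point and is returned
    as-is.  tau2 is always positive.
    """
    if not 0.0 <= sigma0 < 1.0:
        raise ValueError("sigma0 must lie in [0, 1); sigma0 = 1 is singular")
    a, b, w0 = params.alpha, params.beta, params.w0
    one = 1.0 - sigma0
    inv_tau1 = (a - b * w0 * one**2 + a**2 * sigma0**2 * w0 / b) / one
    inv_tau2 = a / one
    tau1 = math.inf if inv_tau1 == 0.0 else 1.0 / inv_tau1
    return tau1, 1.0 / inv_tau2


def jacobian_relaxation_times(params: ModelParams, sigma0: float) -> tuple[float, float]:
    """(tau1, tau2) from the Jacobian of the (Sigma, Delta) flow.

        1/tau1 = alpha + f(s0) - (1-Sigma0) w0 f'(s0)
        1/tau2 = alpha + f(s0)

    Agrees with :func:`relaxation_times` whenever sigma0 solves the
    fixed-point equation (algebraic identity via f' = beta - f^2/beta
    and alpha*Sigma0 = f(s0)(1-Sigma0)); used as an independent
    cross-check of that identity.
    """
    if not 0.0 <= sigma0 < 1.0:
        raise ValueError("sigma0 must lie in [0, 1)")
    s0 = params.w0 * sigma0 + params.h
    f = activation(s0, params)
    fp = activation_deriv(s0, params)
    inv_tau1 = params.alpha + f - (1.0 - sigma0) * params.w0 * fp
    inv_tau2 = params.alpha + f
    tau1 = math.inf if inv_tau1 == 0.0 else 1.0 / inv_tau1
    return tau1, 1.0 / inv_tau2


def fixed_point_rate(params: ModelParams, sigma0: float) -> float:
    """Firing rate R0 = (1 - Sigma0) f(w0*Sigma0 + h) in ms^-1."""
    if not 0.0 <= sigma0 <= 1.0:
        raise ValueError("sigma0 must lie in [0, 1]")
    return (1.0 - sigma0) * activation(params.w0 * sigma0 + params.h, params)


def _make_fixed_point(params: ModelParams, sigma0: float) -> FixedPoint:
    tau1, tau2 = relaxation_times(params, sigma0)
    return FixedPoint(
        sigma0=sigma0,
        s0=params.w0 * sigma0 + params.h,
        r0=fixed_point_rate(params, sigma0),
        tau1=tau1,
        tau2=tau2,
        stable=tau1 > 0.0,
    )


def solve_fixed_points(
    params: ModelParams, *, tol: float = 1e-12, grid: int = 400
) -> list[FixedPoint]:
    """All fixed points Sigma0 in [0, 1] of the mean dynamics.

    Roots of ``alpha*Sigma0 = (1-Sigma0) f(w0*Sigma0 + h)`` located by
    bracketed Brent root finding on a scan grid, using the full tanh
    activation (no small-Sigma0 expansion).  Unstable roots are reported
    with ``stable=False``, not dropped.
    """
    roots: list[float] = []
    if params.h == 0.0:
        roots.append(0.0)  # absorbing state, always a root for h = 0
    xs = np.linspace(0.0, 1.0, grid + 1)
    vals = np.array([_fp_residual(x, params) for x in xs])
    for i in range(grid):
        a, b = xs[i], xs[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if a == 0.0:
            # the origin is an exact root for h = 0; probe just inside it
            # so a second root within the first grid cell is not missed
            a = 1e-12
            fa = _fp_residual(a, params)
        if fa == 0.0 and a > 1e-12:
            roots.append(a)
            continue
        if fa * fb < 0.0:
            roots.append(brentq(_fp_residual, a, b, args=(params,), xtol=tol))
    if vals[-1] == 0.0:
        roots.append(1.0 - 1e-15)
    # deduplicate (grid points landing exactly on roots)
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 10 * max(tol, 1e-12):
            uniq.append(r)
    if not uniq:
        raise RuntimeError("no fixed point found in [0, 1] (invalid parameters?)")
    return [_make_fixed_point(params, r) for r in uniq]


def stable_fixed_point(params: ModelParams) -> FixedPoint:
    """The attractive fixed point (unique in the regime studied, h >= 0)."""
    stable = [fp for fp in solve_fixed_points(params) if fp.stable]
    if not stable:
        raise RuntimeError("no stable fixed point found")
    # at the critical point (h=0, w0=w0c) the root Sigma0=0 is marginal;
    # prefer the largest stable root, which is the attractor for h > 0
    return max(stable, key=lambda fp: fp.sigma0)


def critical_coupling(params: ModelParams, *, verify: bool = False) -> float:
    """Critical net coupling w0c = alpha/beta.

    With ``verify=True`` the sign change of 1/tau1 at Sigma0 = 0 is also
    located numerically by bisection in w0 and required to agree with
    alpha/beta to 1e-10 (a consistency check of the closed form).
    """
    w0c = params.alpha / params.beta

    if verify:
        def inv_tau1_at_zero(w0: float) -> float:
            p = ModelParams.from_balance(
                w0, max(abs(w0), 1.0) * 2.0 + params.w_sum,
                alpha=params.alpha, beta=params.beta, h=0.0, n=params.n,
            )
            t1, _ = relaxation_times(p, 0.0)
            return 1.0 / t1

        lo, hi = 0.0, 10.0 * w0c + 1.0
        # plain bisection on the sign of 1/tau1(Sigma0=0; w0)
        flo = inv_tau1_at_zero(lo)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fm = inv_tau1_at_zero(mid)
            if flo * fm > 0:
                lo, flo = mid, fm
            else:
                hi = mid
            if hi - lo < 1e-14:
                break
        located = 0.5 * (lo + hi)
        if abs(located - w0c) > 1e-10:
            raise AssertionError(
                f"bisected critical coupling {located} != alpha/beta {w0c}"
            )
    return w0c
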