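"""Linear noise approximation around the attractive fixed point.

Writing ``k = N*Sigma_det + sqrt(N)*xi_E`` (and likewise for ``l``), the
system-size expansion of the master equation yields, at order
``sqrt(N)``, a linear Langevin system for the fluctuations
``xi_Sigma = (xi_E + xi_I)/2`` and ``xi_Delta = (xi_E - xi_I)/2``:

    d/dt (xi_Sigma, xi_Delta) = M (xi_Sigma, xi_Delta)
                                + sqrt(alpha*Sigma0) * (eta_Sigma, eta_Delta)

with the triangular relaxation matrix

    M = [[-1/tau1, w_ff], [0, -1/tau2]],

``w_ff = (1-Sigma0)(w_E + w_I) f'(s0)`` the feed-forward coupling of the
E/I imbalance into the total activity.  The stationary covariance solves
the Lyapunov relation ``M sigma + sigma M^T = -alpha*Sigma0 * I`` and the
lagged correlation matrix is ``C(t) = exp(M t) sigma``.  The firing-rate
fluctuation is the linear combination ``xi_R = R_Sigma xi_Sigma +
R_Delta xi_Delta`` with ``R_Sigma = alpha - 1/tau1`` and
``R_Delta = w_ff``, from which the variance, Fano factor and squared
coefficient of variation of ``R`` follow.

Covariances are per-unit-N: ``Var(R) = sigma_RR / N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .model import (
    FixedPoint,
    ModelParams,
    activation,
    activation_deriv,
    stable_fixed_point,
)

__all__ = [
    "LinearNoiseSolution",
    "RateStatistics",
    "build_linear_solution",
    "correlation_matrix",
    "correlation_closed_form",
    "rate_statistics",
    "rate_autocorrelation_analytic",
    "rate_correlation_amplitudes",
]

#: relative agreement demanded between the closed-form covariance and the
#: numerical Lyapunov solve
_LYAPUNOV_RTOL = 1e-10

#: 1/tau degeneracy threshold (ms^-1) for the equal-eigenvalue branch
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class LinearNoiseSolution:
    """Stationary linear-noise solution at a stable fixed point.

    ``cov`` is the 2x2 stationary covariance of (xi_Sigma, xi_Delta),
    dimensionless (per-unit-N); ``noise_amp`` is alpha*Sigma0 (ms^-1),
    the diffusion coefficient of both fluctuation channels.
    """

    params: ModelParams
    fixed_point: FixedPoint
    w_ff: float
    noise_amp: float
    cov: np.ndarray
    r_sigma: float
    r_delta: float

    @property
    def tau1(self) -> float:
        return self.fixed_point.tau1

    @property
    def tau2(self) -> float:
        return self.fixed_point.tau2

    @property
    def relaxation_matrix(self) -> np.ndarray:
        return np.array(
            [[-1.0 / self.tau1, self.w_ff], [0.0, -1.0 / self.tau2]]
        )


@dataclass(frozen=True)
class RateStatistics:
    """Stationary firing-rate statistics in the linear approximation."""

    r0: float  # ms^-1
    sigma_rr: float  # N * Var(R), ms^-2
    fano: float  # sigma_rr / R0, ms^-1
    cv2: float  # sigma_rr / R0^2, dimensionless (N * Var(R/R0))
    degenerate_rate: bool  # True when R0 = 0 and fano/cv2 are +inf


def _closed_form_cov(noise_amp: float, tau1: float, tau2: float, w_ff: float) -> np.ndarray:
    pref = noise_amp / 2.0
    sdd = pref * tau2
    ssd = pref * w_ff * tau1 * tau2**2 / (tau1 + tau2)
    sss = pref * tau1 * (1.0 + w_ff**2 * tau1 * tau2**2 / (tau1 + tau2))
    return np.array([[sss, ssd], [ssd, sdd]])


def build_linear_solution(
    params: ModelParams, fixed_point: FixedPoint | None = None
) -> LinearNoiseSolution:
    """Assemble the stationary linear-noise solution.

    The covariance is computed both in closed form and by numerically
    solving the Lyapunov relation; the two must agree to 1e-10 relative
    (a hard internal consistency check, not a tolerance the caller can
    loosen).

    Raises
    ------
    ValueError
        If the fixed point is repulsive (tau1 <= 0): no stationary
        linear solution exists there.
    """
    fp = fixed_point if fixed_point is not None else stable_fixed_point(params)
    if fp.tau1 <= 0.0 or not math.isfinite(fp.tau1):
        raise ValueError(
            "no stationary linear solution: fixed point is not attractive "
            f"(tau1 = {fp.tau1} ms)"
        )
    w_ff = (1.0 - fp.sigma0) * params.w_sum * activation_deriv(fp.s0, params)
    noise_amp = params.alpha * fp.sigma0
    cov = _closed_form_cov(noise_amp, fp.tau1, fp.tau2, w_ff)

    m = np.array([[-1.0 / fp.tau1, w_ff], [0.0, -1.0 / fp.tau2]])
    cov_num = solve_continuous_lyapunov(m, -noise_amp * np.eye(2))
    scale = max(np.max(np.abs(cov)), np.max(np.abs(cov_num)), 1e-300)
    if np.max(np.abs(cov - cov_num)) > _LYAPUNOV_RTOL * scale:
        raise AssertionError(
            "closed-form and Lyapunov-solver covariances disagree beyond 1e-10"
        )

    r_sigma = params.alpha - 1.0 / fp.tau1
    return LinearNoiseSolution(
        params=params,
        fixed_point=fp,
        w_ff=w_ff,
        noise_amp=noise_amp,
        cov=cov,
        r_sigma=r_sigma,
        r_delta=w_ff,
    )


def _expm_relaxation(sol: LinearNoiseSolution, t: float) -> np.ndarray:
    """exp(M t) via the explicit triangular-matrix exponential."""
    tau1, tau2, w = sol.tau1, sol.tau2, sol.w_ff
    e1 = math.exp(-t / tau1)
    e2 = math.exp(-t / tau2)
    if abs(1.0 / tau1 - 1.0 / tau2) < _DEGENERATE_TOL:
        upper = w * t * e1  # degenerate branch: limit tau2 -> tau1
    else:
        upper = w * tau1 * tau2 * (e1 - e2) / (tau1 - tau2)
    return np.array([[e1, upper], [0.0, e2]])


def correlation_matrix(sol: LinearNoiseSolution, t: float) -> np.ndarray:
    """Lagged correlation matrix C(t) = exp(M t) sigma for t >= 0 (ms).

    Stationarity gives C_xy(-t) = C_yx(t); negative lags are the
    caller's responsibility and rejected here.
    """
    if t < 0.0:
        raise ValueError("lag t must be >= 0 (use C_xy(-t) = C_yx(t))")
    return _expm_relaxation(sol, t) @ sol.cov


def correlation_closed_form(sol: LinearNoiseSolution, t) -> dict[str, np.ndarray]:
    """Entrywise closed forms of C(t) as two-exponential combinations.

    Vectorized over ``t``; returns the four entries keyed
    ``'SS', 'SD', 'DS', 'DD'`` (Sigma/Delta indices).  The non-degenerate
    branch evaluates the explicit amplitudes; the degenerate tau1 = tau2
    branch carries the extra ``t*exp(-t/tau1)`` term.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("lags must be >= 0")
    tau1, tau2, w = sol.tau1, sol.tau2, sol.w_ff
    a0 = sol.noise_amp
    e1 = np.exp(-t_arr / tau1)
    e2 = np.exp(-t_arr / tau2)
    sss, ssd, sdd = sol.cov[0, 0], sol.cov[0, 1], sol.cov[1, 1]
    if abs(1.0 / tau1 - 1.0 / tau2) < _DEGENERATE_TOL:
        upper = w * t_arr * e1
        return {
            "SS": sss * e1 + upper * ssd,
            "SD": ssd * e1 + upper * sdd,
            "DS": ssd * e2,
            "DD": sdd * e2,
        }
    pref = w * tau1 * tau2 / (tau1 - tau2)
    return {
        # C_SS: a0*tau1^2*tau2^2/(2(tau2^2 - tau1^2)) *
        #       [(1/tau1 - tau1/tau2^2 - tau1 w^2) e1 + tau2 w^2 e2]
        "SS": sss * e1 + pref * (e1 - e2) * ssd,
        "SD": ssd * e1 + pref * (e1 - e2) * sdd,
        "DS": ssd * e2,
        "DD": (a0 * tau2 / 2.0) * e2,
    }


def rate_statistics(sol: LinearNoiseSolution) -> RateStatistics:
    """Stationary variance, Fano factor and squared CV of the firing rate.

    ``sigma_rr = R_Sigma^2 sigma_SS + 2 R_Sigma R_Delta sigma_SD
    + R_Delta^2 sigma_DD`` is N times the variance of R (ms^-2).  The
    squared coefficient of variation ``cv2 = sigma_rr / R0^2`` is N times
    the variance of R/R0 and sets the system size below which the linear
    approximation breaks down.  At R0 = 0 both ratios are reported as
    +inf with ``degenerate_rate=True``.
    """
    rs, rd = sol.r_sigma, sol.r_delta
    c = sol.cov
    sigma_rr = rs**2 * c[0, 0] + 2.0 * rs * rd * c[0, 1] + rd**2 * c[1, 1]
    r0 = sol.fixed_point.r0
    if r0 == 0.0:
        return RateStatistics(r0, sigma_rr, math.inf, math.inf, True)
    return RateStatistics(r0, sigma_rr, sigma_rr / r0, sigma_rr / r0**2, False)


def rate_correlation_amplitudes(sol: LinearNoiseSolution) -> tuple[float, float]:
    """Amplitudes (A1, A2) of <xi_R(t) xi_R(0)> = A1 e^{-t/tau1} + A2 e^{-t/tau2}.

    Only meaningful off the degenerate tau1 = tau2 case; A1 + A2 equals
    sigma_rr exactly.
    """
    tau1, tau2, w = sol.tau1, sol.tau2, sol.w_ff
    if abs(1.0 / tau1 - 1.0 / tau2) < _DEGENERATE_TOL:
        raise ValueError("amplitudes undefined in the degenerate tau1 = tau2 case")
    rs, rd = sol.r_sigma, sol.r_delta
    sss, ssd, sdd = sol.cov[0, 0], sol.cov[0, 1], sol.cov[1, 1]
    pref = w * tau1 * tau2 / (tau1 - tau2)
    # collect the e^{-t/tau1} and e^{-t/tau2} coefficients
    a1 = rs**2 * (sss + pref * ssd) + rs * rd * (ssd + pref * sdd)
    a2 = (
        rs**2 * (-pref * ssd)
        + rs * rd * (-pref * sdd + ssd)
        + rd**2 * sdd
    )
    return a1, a2


def rate_autocorrelation_analytic(sol: LinearNoiseSolution, t):
    """Normalized firing-rate autocorrelation C_RR(t), C_RR(0) = 1.

    <xi_R(t) xi_R(0)> = R_Sigma^2 C_SS + R_Sigma R_Delta (C_SD + C_DS)
    + R_Delta^2 C_DD, divided by its t = 0 value (the stationary
    variance sigma_rr).  Vectorized over ``t``.
    """
    c = correlation_closed_form(sol, t)
    rs, rd = sol.r_sigma, sol.r_delta
    raw = rs**2 * c["SS"] + rs * rd * (c["SD"] + c["DS"]) + rd**2 * c["DD"]
    sigma_rr = rate_statistics(sol).sigma_rr
    if sigma_rr == 0.0:
        raise ValueError("zero rate variance: autocorrelation undefined")
    out = raw / sigma_rr
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out)
    return out
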