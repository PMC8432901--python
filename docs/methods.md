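# Methods

## Model

`wccrit` analyses the stochastic Wilson-Cowan model: two homogeneous
populations of `N` excitatory and `N` inhibitory neurons, each neuron a
two-state Markov unit (active/quiescent), all-to-all coupled. An active
neuron deactivates at rate `alpha`; a quiescent neuron activates at rate
`f(s) = beta*tanh(s)` for positive synaptic input `s` and 0 otherwise,
with `s = (w_E k - w_I l)/N + h` set by the active counts `(k, l)`, the
symmetric weights `w_E, w_I`, and a small external input `h`. The
instantaneous firing rate is `R = (1 - (k+l)/2N) f(s)`; it is the order
parameter of the analysis.

All rates are in ms^-1 internally; Hz appears only at reporting
boundaries (x1000). Synaptic inputs and weights are dimensionless: the
millivolt scale of the membrane potential is absorbed into the units of
`s`, which is the convention the activation function assumes.

Default constants follow the regime studied throughout: `alpha = 0.1
ms^-1`, `beta = 1 ms^-1`, `w_E + w_I = 13.8`. The control parameter is
the net coupling `w0 = w_E - w_I`; the critical value is `w0c =
alpha/beta = 0.1`, where (for `h = 0`) the quiescent state exchanges
stability with an active branch and the fixed-point rate `R0` vanishes
continuously.

## Deterministic layer

Fixed points solve `alpha*Sigma0 = (1 - Sigma0) f(w0*Sigma0 + h)` with
the full tanh form, located by bracketed Brent iteration on a scan grid
of [0, 1] (tolerance 1e-12). The quadratic small-activity expansion is
used only as a cross-check near threshold; the 50.3 Hz operating point
is far enough from threshold that the full form is required. Unstable
roots are reported with `stable=False` rather than dropped, so the
stability exchange at `w0c` is itself testable. The relaxation times
come from exact closed forms of the Jacobian eigenvalues; the package
carries both the fixed-point-specialized forms and the raw Jacobian
forms and enforces their algebraic identity to 1e-10 in tests. At the
quiescent point the activation function is not differentiable; the
right-derivative convention `f'(0) = beta` is used, which is the branch
that governs growth of positive perturbations.

## Linear noise approximation

Writing `k = N*Sigma + sqrt(N)*xi_E` (and likewise for `l`) and
expanding the master equation in `N^(-1/2)` gives a linear Langevin
system for `xi_Sigma, xi_Delta` (sum and difference fluctuations) with
triangular relaxation matrix `M = [[-1/tau1, w_ff], [0, -1/tau2]]` and
diffusion `alpha*Sigma0 * I`. The stationary covariance is computed
both in closed form and by `scipy`'s Lyapunov solver, and the two must
agree to 1e-10 relative — a hard internal assertion, not a tunable
tolerance. Lagged correlations use the explicit triangular-matrix
exponential with a dedicated branch for the degenerate case
`tau1 = tau2` (the off-diagonal entry becomes `w_ff * t * e^(-t/tau1)`).

Firing-rate statistics follow from the linearization `xi_R = R_Sigma
xi_Sigma + R_Delta xi_Delta` with `R_Sigma = alpha - 1/tau1` and
`R_Delta = w_ff`. Two caveats discovered while validating against
simulation are worth recording:

* the printed reference values "sigma_RR ~ 6 / 2400 / 4.6e7" are the
  squared coefficient of variation `sigma_RR / R0^2` (N times the
  variance of `R/R0`), not `sigma_RR` in ms^-2; the package exposes
  both under unambiguous names (`sigma_rr`, `cv2`);
* at `w0 = 0.2` the linear sensitivity `R_Sigma` is accidentally close
  to zero (the fixed point sits near the maximum of `R0`), so the slow
  eigen-mode nearly drops out of the *linear* rate correlation and
  second-order terms, which are down by `1/N`, dominate the measured
  correlation up to `N ~ 1e6`. Comparisons between empirical and
  analytic correlation functions at that operating point are therefore
  made at `N = 1e6` and, for tail times, through the same fit window on
  both curves.

## Stochastic engines

The exact engine is a Gillespie simulation. Because neurons within a
population are exchangeable, `(k, l)` is itself a Markov chain with four
channels `{alpha*k, (N-k) f(s), alpha*l, (N-l) f(s)}`; the aggregated
engine simulates that chain in O(1) per event (numba kernels) and is the
default — it reaches `N = 1e6` for minutes of model time on one core. A
literal neuron-level implementation (per-neuron rates, total-rate
waiting time, neuron chosen proportionally to its rate) is retained and
the two are required to agree statistically in tests. With `h = 0` the
state `(0, 0)` is absorbing and the engine legitimately idles to the
horizon.

The Langevin engine integrates the chemical-Langevin form (drift
`-alpha*k + f(s)(N-k)`, noise amplitude `sqrt(alpha*k + f(s)(N-k))`) by
Euler-Maruyama with default step `dt = 1e-3 ms`. The amplitude argument
is clamped at zero below the square root and `(k, l)` are clamped to
`[0, N]` after each step; clamping preserves the drift and is the
standard boundary treatment for chemical Langevin equations.

Defaults tied to model time scales: initial condition `(k, l) =
round(N*Sigma0)`, burn-in `20 * max(tau1, tau2)` discarded before any
stationary statistic (at the near-critical operating point, 3.2e4 ms).
Reproducibility: every kernel takes an explicit integer seed; pipeline
stages split one master seed through `numpy.random.SeedSequence`.

## Avalanche analysis

Spikes are activation events only, E and I pooled. Binned avalanches
are maximal runs of non-empty `delta`-bins (size = spikes in the run,
duration = bins x delta, per-bin profiles kept for shape analysis);
default sensitivity sweep `delta in {1, 2, 4, 8, 16} ms`. Threshold
avalanches are maximal sample stretches with `R > Theta` at sample
resolution; sizes are the spike count (definition 1), the integral of
`R` (2), or the integral of `R - Theta` (3). The integral is the
trapezoidal rule on the excursion padded with the threshold value at the
crossings, which reduces exactly to `dt * sum(R - Theta)` and keeps
single-sample excursions positive. Integral sizes are reported in the
units the rate signal is plotted in (Hz x ms); with that convention the
published lower fitting bound `S_min = 10` falls inside the scaling
regime, whereas in raw spike counts the same bound would sit deep in the
bin-width-dependent region.

Tail exponents are maximum-likelihood estimates, never fits to binned
histograms: the closed form `tau = 1 + n / sum(log(x/xmin))` for
continuous data and numerical maximization of the zeta-normalized
likelihood for integer data, with asymptotic standard error
`(tau-1)/sqrt(n)` and the Kolmogorov-Smirnov distance of the fitted
tail. Calibration against exact inverse-CDF power-law samplers (bias
<= 0.01 at n = 1e5, 2-sigma coverage >= 90% over 100 replicates) is part
of the test suite.

For threshold avalanches with a *finite* threshold the duration of an
excursion is an integer number of sampling steps; those durations are
fitted with the discrete MLE starting at the smallest duration. The
protocol was fixed by calibration on the Ornstein-Uhlenbeck fixture,
where it recovers the first-passage exponent 3/2 to within 0.05, while
continuous MLE at coarser lower bounds is biased upward by the
exponential cutoff at the correlation time.

The size-duration exponent `gamma` is the least-squares slope of
`log<S|T>` vs `log T` over a duration window, by default `T in [80, 200]`
expressed in 1-ms bins, with each duration weighted by the square root
of its avalanche count (long durations hold a handful of heavy-tailed
sizes whose log-mean is noisy and biased). At reduced system size the
finite-size cutoff of the duration distribution can reach into the
default window; `scaling_regime_end` locates the cutoff objectively —
the largest duration at which the empirical survival function stays
within 10% of the power law fitted from `t_min` — and scaling fits
intersect their window with it. Shape collapse rescales the mean per-bin
profile of each duration class by `T^(1-gamma)` against `t/T`; the
collapse quality is the across-class variance of the rescaled curves
normalized by the squared mean amplitude.

## Correlation analysis

The empirical `C_RR(t)` uses FFT autocovariance on the uniform grid with
the plug-in variance in the denominator (stable at long lags), standard
errors from >= 20 non-overlapping batch means, and a correlation time
from the least-squares slope of `ln C` vs `t` restricted to lags where
the correlation lies in a window of its zero-lag peak (default
`[0.01, 0.2]`; the published protocol fits "the long time tail" without
stating a window, so the window is an explicit, documented parameter).

## Synthetic fixtures

Every estimator is validated against ground truth that does not involve
the Wilson-Cowan model: a Galton-Watson branching process with
Poisson(m) offspring (critical exponents 3/2 and 2; any offspring law
with unit mean and finite variance gives the same exponents), an exactly
discretized stationary OU process, exact continuous and discrete
power-law samplers (discrete via vectorized bisection on the zeta CDF,
no rounding approximation), and the exact stationary law of the lumped
chain at `N <= 6` from a null-space solve of the generator (at most 49
states). The Gillespie engine is required to match the latter in total
variation.

## Problem sizes in tests and the acceptance script

The analytic layer is exact and instantaneous. Stochastic checks run at
desk scale, chosen for statistical sufficiency on one core: the
near-critical avalanche catalogs pool several independent 2e5-ms
stretches at `N = 1e6` (sampling step 0.5 ms, well below `tau2 ~ 10
ms`); the mean-rate check integrates 1e7 ms at `N = 1e3`; trend checks
(cutoff vs `N`, correlation-time vs `N` and `h`) use 10 replicates or
1e6-ms records at `N = 1e3..1e5`. At these sizes the tail fits carry a
few thousand samples above the fitting bounds, giving standard errors
of ~0.02-0.03 on the avalanche exponents.

## What the synthetic data do and do not show

The fixtures establish estimator correctness (known exponents, known
correlation times, exact small-N laws) and the simulators' exactness;
the model runs establish that the package reproduces the published
phenomenology at reduced `N`. None of this validates the model against
biological recordings: finite-dimensional connectivity, refractoriness,
synaptic dynamics and measurement noise are all outside the model class.

## Known limitations

* Asymmetric weights, unequal population sizes (the 20%-inhibitory
  variant) and lattice topologies are out of scope.
* Mean quantities at intermediate `N` near criticality (e.g. the time-
  averaged rate at `N = 1e4..1e5`) are dominated by rare large
  avalanches; their sampling variance decays slowly with record length,
  and the measured `N`-dependence of the mean rate is non-monotone even
  though the published endpoint values (at `N = 1e3` and `N = 1e6`) are
  reproduced.
* Threshold-crossing detection is at sample resolution; durations below
  a few sampling steps are correspondingly coarse.
* The stationary `<Delta>` has a systematic O(1/N) offset from zero at
  finite `N` (nonlinear fluctuation coupling); exact balance holds only
  in the large-`N` limit.
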