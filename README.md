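# wccrit — criticality analysis of the stochastic Wilson–Cowan model

`wccrit` is a toolkit for studying whether the avalanche-like activity
of the stochastic Wilson–Cowan model reflects a genuine critical point.
The model describes `N` excitatory and `N` inhibitory two-state neurons
(active/quiescent), all-to-all coupled: an active neuron deactivates at
rate α, a quiescent one activates at rate `f(s) = β tanh(s)` (for
`s > 0`), where `s = (w_E k − w_I l)/N + h` is the synaptic input given
the active counts `(k, l)` and a small external drive `h`. The
instantaneous firing rate

    R = (1 − (k+l)/2N) f(s)

is the order parameter: for `h = 0` its fixed-point value `R₀` vanishes
continuously at the critical coupling `w₀c = α/β` of the net coupling
`w₀ = w_E − w_I`, with diverging Fano factor and correlation time
`τ₁ ∼ 1/(β|w₀ − w₀c|)` — the signature of a second-order transition in
the mean-field branching universality class (avalanche exponents
`τ_S = 3/2`, `τ_T = 2`, size–duration exponent `γ = 2`).

The package provides, as importable modules and a `wccrit` CLI:

* **model** — fixed points, stability times, critical coupling (exact
  closed forms plus bracketed root finding);
* **linear_noise** — the system-size expansion around the attractive
  fixed point: Lyapunov covariance, lagged correlation matrix, firing-
  rate variance / Fano factor / squared CV;
* **simulate** — an exact aggregated Gillespie engine (numba, `O(1)`
  per event, practical to `N = 10⁶`), a literal per-neuron engine for
  fidelity tests, and an Euler–Maruyama integrator of the nonlinear
  Langevin equations;
* **avalanches** — binned and threshold avalanche detection, discrete
  and continuous power-law MLE (Clauset-style) with KS distances,
  size–duration scaling, shape collapse;
* **correlation** — empirical autocorrelation with batch-mean errors
  and exponential-tail correlation times;
* **fixtures** — ground-truth generators (critical branching process,
  Ornstein–Uhlenbeck, exact power-law samplers, small-`N` master-
  equation oracle) against which every estimator is validated.

## Worked example

The deterministic layer at the near-critical operating point
(`α = 0.1 ms⁻¹`, `β = 1 ms⁻¹`, `w_E + w_I = 13.8`):

```sh
$ wccrit analytic --w0 0.1 --h 1e-6
w0c     0.1
sigma0  0.0031572649202125055
R0_Hz   0.3157264920212506
tau1_ms 1581.1202270220447
tau2_ms 9.968427350797874
w_ff    13.756428364115683
sigma_RR        46.94081939799281
fano    148675.58023871298
cv2     470899921.2796691
```

Read: at `w₀ = 0.1 = w₀c` with a tiny drive `h = 10⁻⁶`, the stationary
activity is `Σ₀ ≈ 0.0032`, the fixed-point rate is `R₀ ≈ 0.316 Hz`, the
slow relaxation time is `τ₁ ≈ 1.6 s` (critical slowing down; `τ₂ ≈ 10
ms` is the fast E/I-imbalance mode), and the squared coefficient of
variation `σ_RR/R₀² ≈ 4.7×10⁸` means fluctuations dwarf the mean for
any realizable network size — the avalanche regime (at `h = 10⁻⁵` the
same quantity is `4.6×10⁷`). Far from criticality (`--w0 0.2 --h
1e-3`) the same command prints `R0_Hz ≈ 50.3` and `cv2 ≈ 2.2×10³`.

A stochastic run and its avalanche statistics:

```sh
$ wccrit simulate --w0 0.1 --h 1e-6 --n 1000000 --tmax 150000 \
        --burn-in 32000 --dt-sample 0.5 --seed 7 --out run.txt
$ wccrit avalanches --series run.txt --theta 0.0 --size-def 3 \
        --fit-xmin 10000 --fit-tmin 10
n_avalanches    12187
tau_S   1.5573634883891403  +-  0.02822319732333813   (n=390)
tau_T   2.0636425046666815  +-  0.039667171955194445  (n=719)
```

Avalanches are excursions of the rate signal above a zero threshold;
sizes from the CLI are in spike-equivalent units `N ∫R dt`, so the
lower bound `10⁴` corresponds to 10 in rate-integral units (Hz·ms).
The size and duration tail exponents land on the mean-field
branching-process values 3/2 and 2 — within two standard errors of the
full-scale estimates 1.54 ± 0.03 and 2.04 ± 0.04.

The `run` subcommand executes a whole configured pipeline
(analytic → simulate → avalanches → correlate) from a YAML file and
emits a JSON report with all seeds and settings embedded.

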