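# Methods

## Model

Each cell i carries a three-variable negative-feedback loop describing the
Xenopus embryonic cell-cycle engine: active cyclin–CDK1 (C_i) activates
Polo-like kinase 1 (P_i, active fraction), Plk1 activates the
anaphase-promoting complex (A_i, active fraction), and active APC
inactivates CDK1:

    dC_i/dt = alpha1(t) − beta1 · C_i · A_i^n1 / (K1^n1 + A_i^n1)
    dP_i/dt = alpha2 (1 − P_i) · C_i^n2 / (K2^n2 + C_i^n2) − beta2 P_i
    dA_i/dt = alpha3 (1 − A_i) · P_i^n3 / (K3^n3 + P_i^n3) − beta3 A_i

Plk1 and APC are conserved (total = 1), so P and A live in [0, 1]; C and
the coupling species R are non-negative. N identical cells couple through
a common medium species R, produced from the mean Hill-transformed CDK1
activity and feeding back positively on every cell's CDK1:

    dC_i/dt  +=  k · R^n / (KL^n + R^n)
    dR/dt     =  (k0 / N) · Σ_i C_i^n / (Ka^n + C_i^n) − km · R

Time is in minutes; concentrations are dimensionless. The default
parameter set (packaged as `data/table1.yaml`) is alpha1 = 0.1,
alpha2 = alpha3 = 3, beta1 = 3, beta2 = beta3 = 1, K1 = K2 = K3 = 0.5,
n1 = n2 = n3 = 4, and k = 1, KL = 0.5, n = 3, k0 = 2, Ka = 0.5, km = 1.5,
N = 10. At these settings one free cell cycles every ≈ 3.78 min and the
coupled population, once synchronized, every ≈ 4.315 min. Hill terms are
computed as x^n/(K^n + x^n) with x clamped at 0, so the x = 0 boundary is
exact rather than 0/0.

The cyclin-synthesis rate alpha1 is always a signal object; the constant
default is a constant signal. Four waveforms are supported: constant
(aq), square wave (aq when mod(t, t0) < t1, else 0; defaults t0 = 4,
t1 = 2 min, half-open on-interval so the printed strict inequality is
honoured), half-wave-rectified sinusoid (aq·sin t clipped at 0, angular
frequency fixed at 1 rad/min), and noisy constant (aq + bq·u with
u ~ U[0,1) held piecewise-constant on a 0.1-min grid; bq defaults to
0.001 for aq ≤ 0.01 and 0.01 above). The noise stream is a seeded,
order-independent lookup (bin i maps to the i-th variate of the stream),
so the ODE right-hand side is a deterministic function of (t, seed) and
any integrator sees a consistent signal.

## Numerics

Deterministic integration uses LSODA (stiff-capable, adaptive) at
rtol 1e-8 / atol 1e-10, sampled on a uniform output grid. The time span
is split at square-wave edges (and sinusoid clipping points) and the
solver restarted at each edge; for the noise signal the step is capped at
the noise-grid width instead. Halving the tolerances moves the measured
period by < 0.1%.

Intrinsic noise is modelled as additive: an Euler–Maruyama step of
default dt = 1e-3 min adds independent Gaussian increments of standard
deviation intensity·sqrt(dt) (default intensity 0.001, read as the
diffusion amplitude) to every state component, then clips to the physical
box. This is the simplest reading of an unspecific "inner noise" and is
isolated behind `integrate_stochastic` so it can be swapped.

Initial conditions are nowhere canonical, so they are explicit and
seeded: the default draws each cell's (C, P, A) independently from
U(0, 1) with R(0) = 0. A "clustered" variant places all cells at one
random base point plus independent jitter of configurable spread — a
nearly synchronized start (see below).

Attractor classification discards the first half of a trajectory and
inspects a reference observable (C of cell 1): *steady* when the
peak-to-trough span falls below 1e-4 (well under the O(0.1–1) oscillation
amplitudes), *oscillatory* when at least 10 peaks are found with
inter-peak-interval CV < 1%, otherwise *undetermined*. The period is the
mean inter-peak interval and the amplitude the mean per-cycle max−min.

## Synchronization

The synchronization error takes cell 1 as reference,
E = (1/N) Σ_{i≥2} [(C_i−C_1)² + (P_i−P_1)² + (A_i−A_1)²], implemented
with the 1/N prefactor exactly as defined. Synchrony is declared at
E < 1e-5. Two protocols are distinguished on the default 500-min horizon:

* **attainment** (`sync_time`): the first t at which E stays below the
  threshold for a 20-min hold window (about five periods);
* **persistence** (`synchronized_at_end`): E is below the threshold
  throughout the final 20-min window.

The distinction is forced by the model's geometry. For zero-sum
perturbations the mean-field term is unperturbed (δR = 0), so transverse
stability of the synchronous orbit reduces to the Floquet stability of a
single cell under the common drive k·H(R(t)). Computing those multipliers
shows the high-K2 window ([0.48, 0.57]) is strongly stable
(|μ| ≈ 0.3–0.65), while in the low-K2 window the leading multiplier sits
marginally above 1 (1.000–1.017): synchrony there is not asymptotically
stable but decays so slowly that nearly synchronized cells stay within
the criterion for hundreds of minutes. Interval scans therefore default
to the persistence protocol with clustered initial conditions of spread
0.002, chosen so the initial error (≈ 2e-6) sits just below the 1e-5
criterion; the scan then asks whether synchrony survives the horizon.
A grid point counts as synchronized when all 5 replicate runs hold
synchrony *and* oscillate; synchronized-but-steady points are reported
separately as amplitude death. Under this protocol the K2 axis shows
exactly two synchronized-oscillation windows, ≈ [0.13, 0.21] and
≈ [0.46, 0.57]; the low window's boundaries are protocol-dependent
(spread, horizon) in exactly the way its marginal stability predicts,
so endpoint comparisons carry a ±0.05 allowance.

## Sensitivity analysis

The sensitivity matrix S(t) = ∂x/∂λ obeys the variational system
dS/dt = (∂f/∂x)S + ∂f/∂λ with S(0) = 0, integrated jointly with the
state. Both Jacobians are analytic; tests verify every column against
central finite differences (relative step 1e-6) to 1e-4 of the column
scale over one period. A reserved parameter name `dummy` has zero
direct derivative everywhere and must score exactly zero — a null
control of the whole pipeline.

Scores: per parameter and per observable (C, P, A averaged over cells,
plus R), the time-average of |S| over a 50-min horizon, averaged over
100 repetitions and normalized so each observable's top parameter scores
1. Two randomization modes exist because the published description of
the averaging is ambiguous: the default draws every continuous kinetic
parameter's nominal value from U(0, 1) per repetition (Hill exponents
and N stay fixed — they are structural integers); the "table1" mode
fixes the nominal vector at the default operating point and randomizes
only the initial state. The default mode's top rank is seed-sensitive
(its mean is dominated by heavy-tailed draws); the "table1" mode is
seed-stable and ranks alpha1, Ka, K2, K3, K1, ... for CDK1, in line with
the period-derivative ordering |dT/dλ| at the operating point.

## Bifurcation sweeps

Attractor structure is mapped by brute-force sweeps rather than numerical
continuation. Independent mode integrates n_ic = 5 random starts per
grid point and classifies each; disagreement between replicates (class,
or steady levels differing by more than 0.05) flags bistability.
Continuation mode hands each grid point the previous point's final state;
a forward/backward pair of such sweeps traces hysteresis branches, and
points where the branch extrema of C_1 differ by more than 0.05 are
reported as hysteretic. At the default settings this detects the
coexistence window near k ≈ 1.5 between the oscillatory and high-CDK1
steady branches. `pulse_response` drives the system with a square-wave
cyclin-synthesis pulse and reports whether CDK1 switches branch, sticks,
oscillates, or returns. Exact fold/Hopf coordinates and Floquet spectra
of the full system are out of scope; the undetermined class deliberately
mirrors regions the sweeps cannot resolve.

## Robustness index

Parameters are perturbed by Latin-hypercube sampling (scipy's qmc
engine): each of the 14 continuous kinetic parameters is stratified over
[θ(1−v), θ(1+v)] at variation v = 10% or 20%, one sample per stratum per
dimension, n = 1000 samples by default. Each perturbed population is
simulated under the chosen stimulus from a seeded random start; runs that
hold synchrony through the final window contribute a period (the mean
inter-peak interval — imperfectly periodic, e.g. partially entrained,
responses count, since period dispersion is exactly what the index
measures; non-synchronizing and peakless runs are excluded but tallied in
diagnostics). The index over the N collected periods binned into M equal
regions is r = (1/(N log2 N)) Σ_k b_k log2 b_k, which is 1 when all
periods share one bin and 0 when all N bins are singletons. M is not
fixed a priori: the default bin width is 1% of the nominal 4.315-min
period and M = ceil(range/width) (M = 1 for a degenerate range), tying
"equal regions" to a physical resolution; a fixed M can be passed
instead. Because the binning rule is a package choice, cross-stimulus
comparisons are made as orderings, not as absolute r values; at matched
strength and variation the square-wave input's r exceeds the sinusoid's
and the constant input's (entrainment locks every perturbed population
to the 4-min pulse train).

## Problem sizes in the test suite and acceptance script

The shipped tests and the acceptance script run at the study's own scales
where that is cheap (N = 10, 500-min horizons, the full K2 scan at step
0.01 with 5 replicates, 100 sensitivity repetitions) and at reduced
scales where the full figure-level experiment is a long Monte-Carlo
campaign: the robustness ordering is checked at n = 20 samples and one
matched strength (0.15) at 10% variation, and examples use small grids.
These sizes are stated in the relevant docstrings; rerunning at larger n
sharpens the estimates without changing any ordering asserted here.

## Known limitations

* The synthetic initial-condition and perturbation distributions are the
  study's convention (uniform boxes, relative LHS bands); real embryonic
  populations are not sampled this way, so passing tests demonstrate
  internal reproducibility of the model analysis, not biological fit.
* Identical cells only: heterogeneity enters through initial conditions
  and parameter perturbations shared by a whole population, never per
  cell.
* The intrinsic-noise model is additive and component-uniform; chemical
  Langevin or discrete-event noise would scale with concentrations.
* The low-K2 synchronization window is marginally unstable; any
  finite-horizon criterion (including this package's) reports
  protocol-dependent endpoints there.
* The sensitivity averaging behind the published ranking is
  underdetermined; both implemented modes are documented above and the
  package treats rankings, not score values, as meaningful.
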