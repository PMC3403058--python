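# cyclesync

Simulation and analysis of a population of globally coupled Xenopus
embryonic cell-cycle oscillators.

Each cell runs a three-variable negative-feedback loop — active
cyclin–CDK1 (C) activates Plk1 (P), Plk1 activates the
anaphase-promoting complex APC (A), and APC inactivates CDK1:

    dC_i/dt = α1(t) − β1 C_i A_i^n1 / (K1^n1 + A_i^n1) + k R^n/(KL^n + R^n)
    dP_i/dt = α2 (1−P_i) C_i^n2 / (K2^n2 + C_i^n2) − β2 P_i
    dA_i/dt = α3 (1−A_i) P_i^n3 / (K3^n3 + P_i^n3) − β3 A_i
    dR/dt   = (k0/N) Σ_i C_i^n/(Ka^n + C_i^n) − km R

N identical cells interact only through the shared medium species R
(mean-field coupling). The package is for modellers studying collective
rhythms in multicellular systems: when does a population of cell-cycle
oscillators beat as one, how fast, and how robustly under different
cyclin-synthesis stimuli (constant, square-wave, sinusoidal, noisy)?

It provides, as a library plus a thin `cyclesync` CLI:

* deterministic (LSODA) and intrinsic-noise (Euler–Maruyama)
  integration with period/amplitude/attractor extraction;
* the synchronization error E = (1/N) Σ_{i≥2} ‖(C,P,A)_i − (C,P,A)_1‖²,
  synchronization times, and parameter scans for synchronization
  intervals;
* forward sensitivity analysis via the variational system
  dS/dt = (∂f/∂x)S + ∂f/∂λ with analytic Jacobians;
* brute-force bifurcation sweeps with bistability and hysteresis
  detection, plus pulse-switching experiments;
* an entropy-based robustness index of the period distribution under
  Latin-hypercube parameter perturbations,
  r = (1/(N log₂N)) Σ_k b_k log₂ b_k ∈ [0, 1].

## Worked example

Ten cells starting from scattered random phases, default parameters:

```python
from cyclesync import (table1, table1_coupling, draw_initial_conditions,
                       integrate_deterministic, summarize_oscillation,
                       sync_time)

params, coupling = table1(), table1_coupling()     # N = 10 cells
x0 = draw_initial_conditions(coupling, seed=42)
traj = integrate_deterministic(params, coupling, params.alpha1, x0,
                               t_end=300.0, dt_out=0.01)
res = sync_time(traj)
summ = summarize_oscillation(traj)
print(res.synchronized, round(res.sync_time, 1), round(summ.period, 3))
```

prints

```
True 22.3 4.316
```

— the population crosses the synchronization criterion (E < 1e-5,
held for 20 min) at t ≈ 22.3 min and then beats with a common period of
≈ 4.316 min, slower than the ≈ 3.785-min rhythm of an uncoupled cell
(run `examples/01_single_oscillator.py`) because the R feedback lengthens
the loop. The `examples/` directory holds one short script per
capability — stimuli, interval scans, sensitivity ranking, hysteresis,
robustness, noise-driven regime switching — each printing a few numbers
and what they mean; `docs/methods.md` documents the model, the numerical
choices, and the protocol behind each analysis.

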