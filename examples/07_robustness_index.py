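"""Robustness of the synchronized rhythm under parameter perturbation.

Kinetic parameters are jittered by Latin-hypercube sampling within ±10%
of nominal; each perturbed population is simulated and the synchronized
period recorded.  The entropy-like index r is 1 when all periods land in
one bin (a perfectly reproducible rhythm) and 0 when all differ.  The
square-wave stimulus entrains every perturbed population to its own
4-min beat, so its r tops the constant and sinusoidal inputs.
"""

from cyclesync import SignalSpec, robustness_experiment

print("stimulus   r      synchronized/sampled")
for kind in ("square", "constant", "sine"):
    res = robustness_experiment(SignalSpec(kind=kind, aq=0.15),
                                variation=0.10, n=20, seed=5,
                                t_end=300.0, dt_out=0.02)
    r = f"{res.r:.3f}" if res.r is not None else " n/a "
    print(f"{kind:<10} {r}   {res.n_synchronized}/{res.n_samples}")
print("\n(r = 1: all perturbed populations keep an identical period)")
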