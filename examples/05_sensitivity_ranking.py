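"""Forward sensitivity ranking of the kinetic parameters.

Integrates the variational system dS/dt = (df/dx) S + df/dlambda jointly
with the state and scores each parameter by the time-averaged |S| per
observable, averaged over random repetitions and normalized to the top
parameter.  Around the default operating point ("table1" mode) the
activation thresholds (K-type parameters) and the cyclin-synthesis rate
dominate: small shifts in these change the period the most.
"""

import numpy as np

from cyclesync import sensitivity_scores
from cyclesync.sensitivity import SENSITIVITY_PARAMS

run = sensitivity_scores(n_draws=5, horizon=20.0, seed=0,
                         nominal="table1")

print("normalized sensitivity of CDK1 (top 8 parameters):")
row = run.normalized_scores[0]
for j in np.argsort(-row)[:8]:
    print(f"  {SENSITIVITY_PARAMS[j]:<7} {row[j]:.3f}")
print("\n(1.0 marks the most sensitive parameter for this observable)")
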