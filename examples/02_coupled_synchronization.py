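"""Synchronization of ten globally coupled cells.

Ten identical oscillators start from scattered random phases and interact
only through the shared medium species R.  The synchronization error E
(sum of squared deviations from cell 1) collapses below the 1e-5
criterion, after which every cell beats with a common period (~4.315 min,
longer than the free-running 3.78 min because the R feedback slows the
loop).
"""

from cyclesync import (draw_initial_conditions, integrate_deterministic,
                       summarize_oscillation, sync_time, table1,
                       table1_coupling)

params, coupling = table1(), table1_coupling()   # N = 10 cells
x0 = draw_initial_conditions(coupling, seed=42)  # scattered phases
traj = integrate_deterministic(params, coupling, params.alpha1, x0,
                               t_end=300.0, dt_out=0.01)

res = sync_time(traj)
summ = summarize_oscillation(traj)
print(f"synchronized : {res.synchronized}")
print(f"sync time    : {res.sync_time:.1f} min  "
      "(first time E stays below 1e-5)")
print(f"final error  : {res.error_series[-1]:.2e}")
print(f"period       : {summ.period:.3f} min (collective rhythm)")
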