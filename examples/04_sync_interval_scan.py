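"""Synchronization windows of the Plk1-activation threshold K2.

K2 is the Hill coefficient of CDK1-driven Plk1 activation.  The coupled
system holds synchronized oscillation in two disjoint windows of K2: a
weakly stable low window (synchrony persists over the 500-min horizon
only from nearly synchronized starts) and a strongly stable window around
the default K2 = 0.5.  This example scans a segment of each window at a
coarse step; the full scan lives in the acceptance script.
"""

import numpy as np

from cyclesync import scan_sync_interval, table1, table1_coupling

params, coupling = table1(), table1_coupling()

for label, grid in [("low window", np.round(np.arange(0.16, 0.221, 0.02), 3)),
                    ("high window", np.round(np.arange(0.48, 0.571, 0.03), 3))]:
    scan = scan_sync_interval("K2", grid, params, coupling, n_ic=3,
                              t_end=500.0, dt_out=0.05, seed=1)
    print(f"{label}: grid {grid.tolist()}")
    for v, s, per in zip(scan.grid, scan.synchronized_mask, scan.period):
        p = f"period {per:.2f} min" if s else "not synchronized"
        print(f"  K2={v:.2f}: {p}")
    print(f"  intervals found: {scan.intervals}")
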