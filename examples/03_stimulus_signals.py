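"""The four cyclin-synthesis stimuli and their effect on synchronization.

Cyclin synthesis alpha1(t) can be constant, a square-wave pulse train
(on t1 = 2 of every t0 = 4 min), a half-wave-rectified sinusoid, or a
noisy constant.  The square wave synchronizes the scattered population
fastest -- each pulse kicks every cell simultaneously.
"""

from cyclesync import (SignalSpec, draw_initial_conditions,
                       integrate_deterministic, sync_time, table1,
                       table1_coupling)

params, coupling = table1(), table1_coupling()
signals = [
    SignalSpec(kind="constant", aq=0.1),
    SignalSpec(kind="square", aq=0.6, t0=4.0, t1=2.0),
    SignalSpec(kind="sine", aq=1.0),
    SignalSpec(kind="noise", aq=0.01, seed=0),   # bq resolves to 0.001
]

print("stimulus   alpha1(t=1)  sync time (min)")
for sig in signals:
    x0 = draw_initial_conditions(coupling, seed=7)
    traj = integrate_deterministic(params, coupling, sig, x0,
                                   t_end=200.0, dt_out=0.02)
    res = sync_time(traj)
    when = f"{res.sync_time:7.1f}" if res.synchronized else "   (no)"
    print(f"{sig.kind:<10} {sig(1.0):>10.4f}  {when}")
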