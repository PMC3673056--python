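"""Two fates for a cooperative population invaded by tactical deceivers.

Integrates the replicator dynamics from a conditional-cooperator (CC)
population seeded with 1% tactical deceivers (TD) and 1% honest defectors
(HD), under efficient cheap deception (q = 0.8, d = 0.1) and under
inefficient costly deception (q = 0.5, d = 0.45).
"""

import numpy as np

import tacdec as td

start = td.PopulationState(0.98, 0.01, 0.01)
for name, params in [
    ("efficient deception", td.GameParams(b=1.5, c=0.5, s=0.2, d=0.1,
                                          q_mode="constant", q=0.8)),
    ("costly deception", td.GameParams(b=1.5, c=0.5, s=0.2, d=0.45,
                                       q_mode="constant", q=0.5)),
]:
    regime = td.classify_regime(params)
    traj = td.integrate(start, params, t_end=500.0)
    x = traj.states[-1]
    print(f"{name}: regime = {regime.label}")
    print(f"  final frequencies  x_CC={x[0]:.4f}  x_TD={x[1]:.4f}  x_HD={x[2]:.4f}")

# Deceivers pass through transiently; where they dominate CCs, cooperation
# collapses to honest defection. Where they cannot invade, the CC population
# shrugs off the incursion: the endpoint tells you which Nash equilibrium won.
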