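"""Coexistence of cooperators and deceivers under learned detection.

When detection improves as deception becomes common (q = 1 - x_TD), the
deceivers' advantage is negatively frequency dependent and a stable interior
mixture can appear on the CC-TD edge.
"""

import tacdec as td

params = td.GameParams(b=1.5, c=0.5, s=0.2, d=0.1, q_mode="freq_dependent")
rep = td.find_mixed_equilibrium(params)

print(f"x_CC* = {rep.state.x_cc:.6f}  (deceivers: {rep.state.x_td:.6f})")
print(f"stable: {rep.stable}, eigenvalue real parts: "
      f"{[round(e.real, 6) for e in rep.eigenvalues]}")
print(f"honest-defector pressure b(1-s)x_CC*^2 = {rep.hd_margin + params.d:.3f} "
      f"vs deception cost d = {params.d}")
print(f"HD can invade the mixture: {rep.hd_invadable}")

# Half the population cooperates conditionally, half deceives; both earn the
# same payoff. Because b(1-s)x_CC*^2 = 0.3 exceeds d = 0.1, honest defectors
# earn less than the mixture and the equilibrium resists their invasion.
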