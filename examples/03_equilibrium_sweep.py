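"""Where can deceivers and cooperators coexist in parameter space?

Sweeps the benefit of cooperation b and the cost of deception d at fixed
c = 0.5 for three slip rates s, recording the stable HD-resistant mixed
equilibrium where it exists.
"""

import numpy as np

import tacdec as td

b_values = np.linspace(0.6, 3.0, 50)
d_values = np.linspace(0.005, 0.495, 50)

for s in (0.1, 0.2, 0.3):
    grid = td.sweep_equilibrium(b_values, d_values, s=s, c=0.5)
    n_stable = int(np.isfinite(grid.x_cc_star).sum())
    mean_cc = float(np.nanmean(grid.x_cc_star))
    print(f"s = {s}: {n_stable}/2500 cells with a stable mixture, "
          f"mean x_CC* = {mean_cc:.3f}")

# The coexistence region shrinks as s grows: leakier conditionality hands
# defectors more free cooperation, so concealing defection buys less.
# Within the region, cheaper deception (small d) means more deceivers.
grid = td.sweep_equilibrium([1.5], [0.05, 0.15, 0.25, 0.35, 0.45], s=0.2, c=0.5)
print("x_CC* at b=1.5 as d rises:",
      np.round(grid.x_cc_star[0], 3))
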