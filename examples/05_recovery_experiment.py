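"""Calibration of the comparative stage on synthetic data.

Runs a small parameter-recovery experiment (true cooperativeness slope 0.9,
50 replicates of 100-tip trees) and a null-effect experiment (slope 0,
200 replicates at the 24-species scale), reporting estimate bias and the
false-positive rate.
"""

import numpy as np
from scipy import stats

import tacdec as td

estimates = []
for r in range(50):
    tree, table, truth = td.simulate_comparative_dataset(
        td.SyntheticSpec(seed=1000 + r, n_tips=100)
    )
    fit = td.pgls_fit(tree, table, model="ratio_model")
    estimates.append(fit.params["cooperativeness"])
print(f"mean estimated slope: {np.mean(estimates):.3f} (truth 0.9), "
      f"sd {np.std(estimates, ddof=1):.3f}")

null_beta = {"intercept": 1.0, "cooperativeness": 0.0, "log_research_effort": 0.5}
rejections = 0
for r in range(200):
    tree, table, _ = td.simulate_comparative_dataset(
        td.SyntheticSpec(seed=2000 + r, n_tips=24, beta=null_beta)
    )
    fit = td.pgls_fit(tree, table, model="ratio_model")
    rejections += fit.pvalues["cooperativeness"] < 0.05
print(f"false-positive rate at p < 0.05, n = 24: {rejections / 200:.3f} "
      f"(nominal 0.05)")

# An unbiased estimator and a near-nominal false-positive rate mean that a
# significant cooperativeness effect found with this machinery on real data
# is not an artifact of the regression's phylogenetic assumptions.
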