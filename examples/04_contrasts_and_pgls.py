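"""The comparative test: does cooperativeness predict deception rates?

Simulates a 24-species dataset with a true cooperativeness effect of 0.9 on
ln(deception count + 1), then fits the phylogenetic regression
log(deception + 1) ~ cooperativeness + neocortex ratio + log(research effort)
at Pagel's lambda = 1 and cross-checks it against a through-origin regression
on independent contrasts.
"""

import tacdec as td
from tacdec.comparative import contrasts_regression, partial_out_contrasts

tree, table, truth = td.simulate_comparative_dataset(td.SyntheticSpec(seed=42, n_tips=24))
print(f"true cooperativeness slope: {truth['beta']['cooperativeness']}")

fit = td.pgls_fit(tree, table, model="ratio_model")
print("\nPGLS (lambda = 1):")
print(fit.summary_frame().round(4).to_string())

alt = contrasts_regression(tree, table, model="ratio_model")
print(f"\ncontrasts-regression cooperativeness slope: "
      f"{alt.params['cooperativeness']:.10f} (identical route check)")

pairs = partial_out_contrasts(tree, table, "cooperativeness",
                              ["neocortex_ratio", "log_research_effort"])
slope = float(pairs.x @ pairs.y / (pairs.x @ pairs.x))
print(f"slope of partialled contrasts: {slope:.10f}")

# The cooperativeness coefficient estimates how much ln(deception + 1) rises
# per extra cooperative behaviour, holding brain size and research effort
# fixed and treating species as phylogenetically correlated observations.
# All three routes (GLS, contrasts, partialled contrasts) agree exactly.
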