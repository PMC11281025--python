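"""Probabilistic risk: Monte Carlo propagation of input uncertainty.

Samples intake rate and body weight (normal), exposure frequency
(triangular 180/350/360) and per-metal concentrations (moment-fitted
lognormals) 10,000 times, and reports the resulting THI and TCR
distributions with exceedance probabilities at the risk thresholds.
"""

from wetlandrisk import MCConfig, run_mc

result = run_mc(MCConfig(seed=7, n_iterations=10_000))

summary = result.summary()
cols = ["population", "group", "output", "mean", "sd", "p5", "p50", "p95"]
totals = summary[summary["output"].isin(["THI", "TCR"])]
print(totals[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

print("\nexceedance probabilities:")
for pop, group in result.frames:
    p_thi = result.exceedance(pop, group, "THI", 1.0)
    p_tcr = result.exceedance(pop, group, "TCR", 1e-4)
    print(f"  {group}/{pop}: P(THI > 1) = {p_thi:.1%}   P(TCR > 1e-4) = {p_tcr:.1%}")

# Children's THI distributions straddle 1 (a sizable probability of
# potential non-carcinogenic risk), while adult TCR crosses the 1e-4
# "moderate" cancer-risk line only in the upper tail.
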