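"""Which inputs drive the risk? Contribution-to-variance ranking.

Runs the default Monte Carlo and ranks every sampled input (per-metal
concentrations, IR, EF, BW) by its signed, normalized squared Spearman
correlation with THI and TCR.
"""

from wetlandrisk import MCConfig, analyze_mc, run_mc

result = run_mc(MCConfig(seed=7, n_iterations=100_000, groups=("rural",)))

for output in ("THI", "TCR"):
    for sens in analyze_mc(result, output):
        print(f"\n{output} / {sens.population} ({sens.group}):")
        for name, pct in sens.ranked():
            print(f"  {name:4s} {pct:+7.2f} %   (rho = {sens.correlations[name]:+.3f})")

# Arsenic concentration dominates both endpoints; intake rate and exposure
# frequency follow. Body weight sits in the denominator of the dose
# equations, so its correlation is negative — visibly for children, whose
# 0.15 kg spread is larger relative to their 20 kg mean; for adults the
# BW signal is below this run's Monte Carlo resolution (|rho| ~ 0.004 vs
# a sampling SE of ~0.003), so its printed sign can fluctuate.
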