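# wetlandrisk

Contamination indices and probabilistic human-health risk assessment for
heavy metal(loid)s — Hg, As, Cu, Zn, Pb, Cd — in the overlying water of
small wetlands.

Small wetlands (ponds, small lakes, channels under ~8 ha) are easily
overlooked in water-quality monitoring, yet they accumulate contaminants
readily: low dilution, stagnant flow, and direct agricultural runoff. This
package implements the full assessment chain used for a 36-sample survey
of urban and rural small wetlands in an arid-zone city (20 urban, 16 rural
samples of overlying water): regulatory contamination indices, a US-EPA
style exposure and risk model for children and adults, Monte Carlo
uncertainty propagation, and a contribution-to-variance sensitivity
ranking. Because the survey's raw per-sample data are not public, the
package also ships a synthetic sample generator that reproduces the
published group summary statistics, so the entire pipeline is runnable and
testable out of the box.

## The model

**Contamination.** For each metal *i* with concentration *Cᵢ* (µg/L) and
Class II regulatory threshold *Sᵢ* (GB 3838-2002),

    Pᵢ = Cᵢ / Sᵢ          NPI = sqrt((P²max + P²ave) / 2)

The Nemerow pollution index (NPI) mixes the worst single-factor index with
the mean, so one badly exceeding metal (here Hg, whose group means exceed
the 0.05 µg/L threshold by 3.2× urban and 5.0× rural) drives the composite.
Classes: < 0.7 none, ≤ 1 slight, ≤ 2 light, ≤ 3 moderate, > 3 high.

**Exposure.** Chronic daily intake (µg/kg/d) by two routes, for children
and adults:

    CDI_ing  = C · IR · EF · ED / (BW · AT)
    CDI_derm = C · SA · Kp · T_event · EV · EF · ED · 10⁻³ / (BW · AT)

**Risk.** Per metal, HQ = CDI_ing/RfD_ing + CDI_derm/RfD_derm and
THI = Σ HQ (values > 1 flag potential non-carcinogenic risk);
CR = CDI_ing·SF_ing + CDI_derm·SF_derm and TCR = Σ CR for the metals with
slope factors (As and Cd), classified from "very low" (< 10⁻⁶) to
"extremely high" (> 0.1).

**Uncertainty.** IR and BW are normal, EF is triangular(180, 350, 360)
d/y, concentrations are detection-limit-truncated lognormals fitted to the
group mean/SD by moment matching. A seeded Monte Carlo engine propagates
all of them jointly and reports distributions, percentiles, and exceedance
probabilities. Sensitivity is the signed, normalized squared Spearman rank
correlation between each sampled input and THI/TCR ("contribution to
variance").

## Worked example

```python
from wetlandrisk import assess_point_risk, default_registry, survey

registry = default_registry()
rr = assess_point_risk(survey.GROUP_MEAN_CONCENTRATIONS["rural"], "adults", registry)
print(f"THI = {rr.thi:.3f} ({rr.thi_flag})")
print(f"TCR = {rr.tcr:.3e} ({rr.tcr_class})")
for m, cr in rr.cr.items():
    print(f"  CR_{m} = {cr:.3e}  ({rr.cr_shares[m]:.1f}% of TCR)")
```

prints

```
THI = 0.519 (no significant non-carcinogenic risk)
TCR = 7.165e-05 (low risk)
  CR_As = 6.317e-05  (88.2% of TCR)
  CR_Cd = 8.478e-06  (11.8% of TCR)
```

i.e. for adults exposed to rural group-mean concentrations, the summed
non-carcinogenic hazard stays below 1, while the incremental lifetime
cancer risk of ~7×10⁻⁵ sits in the "low" band (between 1 in a million and
1 in ten thousand), ~88 % of it from arsenic. The `examples/` directory
walks through each capability: pollution indices, point risk, synthetic
sample generation, Monte Carlo, and sensitivity ranking.

A thin CLI wraps the same library for batch runs:

```
wetlandrisk simulate --profile rural --seed 1 --out samples.csv
wetlandrisk assess samples.csv --out-dir out/
wetlandrisk mc --group rural --population adults --iterations 10000 --seed 7 --out-dir mc/
```

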