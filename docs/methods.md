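# Methods

## Scope and data

The package assesses six heavy metal(loid)s (Hg, As, Cu, Zn, Pb, Cd) in
wetland overlying water for two population groups (children, adults) and
two site groups (urban, rural small wetlands). The underlying survey
published only group-level summary statistics — per-metal max, min, mean,
SD for 20 urban and 16 rural samples, plus the group-average single-factor
pollution indices — and those summaries, recorded verbatim in
`wetlandrisk.survey`, are the package's inputs. Everything downstream
(synthetic samples, indices, risks, Monte Carlo) is recomputed from them
at run time.

## Contamination indices

`P_i = C_i / S_i` against the Class II thresholds of the Chinese
surface-water standard (GB 3838-2002): Hg 0.05, As 50, Cu 1000, Zn 1000,
Pb 10, Cd 5 µg/L. The Nemerow composite is
`NPI = sqrt((P_max² + P_ave²)/2)`, which always lies between the mean and
the maximum of the single-factor indices and is homogeneous of degree one
in the concentrations (both properties are asserted as tests).

Group-level indices are computed from group-mean concentrations. Since
`P_i` is linear in concentration, the group-mean index equals the mean of
per-sample indices; it is also the only reading under which the published
group NPIs (2.31 urban, 3.58 rural) are recovered exactly from the
published average index rows. A per-sample-then-summarize view is exposed
alongside.

**Boundary convention.** The published class table leaves values exactly
on a cut (e.g. `P_i = 0.7`) unassigned between "< 0.7" and "0.7 < P_i ≤ 1".
We use closed upper bounds — [0, 0.7], (0.7, 1], (1, 2], (2, 3], (3, ∞) —
so a value on a cut joins the *less* severe class, consistent with the
"≤" pattern of the published upper rows. The cancer-risk scheme instead
keeps the published half-open form verbatim: [0, 10⁻⁶), [10⁻⁶, 10⁻⁴),
[10⁻⁴, 10⁻³), [10⁻³, 0.1), [0.1, ∞).

## Exposure and risk model

Standard EPA two-route water-exposure equations (see README for the
formulas). Parameter defaults (children / adults): IR ~ N(1.25, 0.3) /
N(1.95, 0.3) L/d; EF ~ Triangular(180, 350, 360) d/y; ED 2.5 / 26 y;
BW ~ N(20, 0.15) / N(70, 0.15) kg; AT 912.5 / 9490 d (non-cancer) and
25,550 d (cancer, both); SA 7422 / 18,182 cm²; T_event 0.58 / 1 h;
EV 1/d. Dermal permeabilities Kp: 10⁻³ cm/h for Hg, As, Cu, Cd; 6×10⁻⁴
for Zn; 10⁻⁴ for Pb. Reference doses and slope factors are in
`data/default_config.yaml`; only As and Cd carry slope factors, so TCR
sums over those two and the report lists the metals skipped.

All doses, HQs and CRs are kept in µg/kg/d and (µg/kg/d)⁻¹ throughout;
the 10⁻³ in the dermal equation converts the absorbed water volume from
cm³ to litres. The averaging time is selected by endpoint (non-cancer vs
cancer), never by population.

**Known caveat: body-weight SD.** The published BW spread is 0.15 kg for
both populations — implausibly small for a real population (plausible
values are ~2–10 kg). It is implemented exactly as published and is
overridable in the config file. Its smallness matters mainly for
sensitivity analysis (below).

**Point-estimate mode.** Normal parameters collapse to their mean,
triangular EF to its most probable value (350 d/y), and concentrations to
group means. In this mode the package reproduces the published rural TCRs
within 0.5 % (adults 7.16×10⁻⁵ vs 7.13×10⁻⁵ published; children
1.526×10⁻⁵ vs 1.53×10⁻⁵), which both anchors the implementation and
indicates the published TCRs are essentially mode-EF point values.

**Published values not recoverable from the stated model.** The published
simulation-mean THIs (0.46/0.57 adults, 1.02/1.25 children), the HQ
severity orderings placing Hg above Cu, the urban As CR of 6.31×10⁻⁵
(which matches the *rural*-mean derivation — the urban/rural labels appear
swapped), and the claim that Cd CRs are below 10⁻⁶ (contradicting the
same section's printed 8.26×10⁻⁶) cannot be derived from the published
equations, parameters and summary statistics. The package does not tune
toward them; correctness for the probabilistic machinery is instead
established by property tests: degenerate Monte Carlo equals the
deterministic oracle exactly, per-iteration THI/TCR conserve their sums
row-wise, and means of linear-in-inputs outputs match analytic
expectations within Monte Carlo error.

## Synthetic sample generator

Concentrations are modelled per metal as lognormal — the conventional
choice for positive, right-skewed environmental concentrations (observed
CVs up to 1.29) — with natural-scale moments matched to the published
group mean/SD via `σ² = ln(1+(sd/mean)²)`, `µ = ln(mean) − σ²/2`, and
truncated below at the instrument detection limits (Hg 0.04, As 0.30,
Cu 0.08, Zn 0.67, Pb 0.09, Cd 0.05 µg/L) by rejection sampling.

With `moment_match=True` the realized draws are post-adjusted: log-values
are standardized, an exponent `b` is solved (Brent's method) so the sample
CV of `exp(b·u)` hits the target CV, a multiplicative factor restores the
mean, and the result is re-clipped at the detection limit; the cycle runs
at most 5 times and warns with the achieved moments if the 0.5 % tolerance
is unmet (it is met for all metals and seeds exercised in the tests).

What the generator does *not* emulate: inter-metal correlation (nothing
published to honour; metals are independent), spatial or seasonal
structure, and the empirical shape near the regulatory threshold — the
standard-exceeding ratio is emergent from the lognormal, so the published
80 %/81.25 % Hg exceedance ratios are not reproduced by matched moments
alone. Passing tests therefore demonstrate the pipeline's arithmetic and
statistical contracts on realistic marginals, not distributional fidelity
of the unpublished raw data. pH and EC are uniform pass-through metadata
within the observed ranges (6.84–8.36; 423–5820 µS/cm).

## Monte Carlo engine

Defaults: 10,000 iterations (configurable, ≥ 100), a required integer
seed, lognormal concentration mode. Each iteration shares one parameter
realization (IR, EF, BW) across metals and groups for a population — a
person has one body weight — which is what makes input–output rank
correlations meaningful. ED, SA, T_event and EV stay at point values; IR
and BW are truncated at 1 % of their means (a guard floor; with the
default SDs truncation is never active for BW and negligible for IR), EF
is capped at 366 d/y. Sub-streams are spawned per population and per
group from fixed indices, so adding a group to a run leaves other groups'
draws untouched, and identical configurations reproduce bit-identically.
Concentrations can also enter as joint resampling of provided sample rows
(`empirical`, preserving correlation) or as fixed group means. A `fix_ef`
switch holds EF at 350 d/y, reproducing the point-estimate behaviour the
published TCRs reflect.

Summaries (mean, SD, percentiles 1/5/25/50/75/95/99, exceedance
probabilities) are always computed from raw draws, never from rounded
values.

## Sensitivity analysis

Contribution to variance: `sign(ρ_k) · 100 · ρ_k² / Σ_j ρ_j²` over the
Spearman correlations ρ between each sampled input (per-metal
concentrations, IR, EF, BW) and the output (THI or TCR). Absolute
contributions sum to 100 %; the measure is invariant under monotone
transforms of any input and under input reordering (both property-tested).
Constant inputs report ρ = 0 with a warning rather than aborting.

On default runs arsenic dominates both endpoints (its concentration CV,
0.43–0.67, is the largest variance source), IR and EF follow, and BW is
the only negative driver. Because the published BW SD is 0.15 kg, the
adult BW correlation is genuinely tiny (|ρ| ≈ 0.003–0.005): resolving its
sign requires ~10⁶ iterations (3-SE rule, n ≳ (3/ρ)²), which is what the
sign-and-ordering test uses; routine runs at 10⁴ iterations cannot
distinguish it from zero, and the published adult sensitivity of −2.71 %
is consistent only with a much larger BW spread than the one published.

## Problem sizes

Tests use the survey's own sample counts (20/16), 10⁴ iterations for
convergence checks (Monte Carlo SE bands at 3 SE), 200 replicates for the
sampling-distribution check of the generator (2 SE band), and 10⁶
iterations for the one statistically demanding sensitivity-sign check.

## Numerical notes

- Classification of totals always uses full-precision values; rounding to
  the published 2-decimal format happens only at display.
- `nemerow_index` of an empty vector, negative indices, zero thresholds,
  missing metal columns and NaN concentrations raise with the offending
  sample/metal named.
- Moment inversion uses `log1p` for CV² to keep precision at small CVs.
- The config round-trip (registry → YAML → registry) is exact, asserted
  as a test.
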