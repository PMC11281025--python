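"""Monte Carlo engine: determinism, conservation, convergence, degeneracy."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from wetlandrisk import (
    DistributionSpec,
    MCConfig,
    assess_point_risk,
    cumulative_frequency,
    exceedance_probability,
    run_mc,
    sample_realization,
)
from wetlandrisk import survey

RURAL = survey.GROUP_MEAN_CONCENTRATIONS["rural"]


def _point_spec(spec):
    return DistributionSpec("point", {"value": spec.point_value()})


def _pointify(registry, keep=()):
    """Registry copy with every sampled exposure parameter collapsed
    to its point value, except those named in ``keep``."""
    profiles = {}
    for pop, p in registry.profiles.items():
        profiles[pop] = dataclasses.replace(
            p,
            ir=p.ir if "ir" in keep else _point_spec(p.ir),
            ef=p.ef if "ef" in keep else _point_spec(p.ef),
            bw=p.bw if "bw" in keep else _point_spec(p.bw),
        )
    return dataclasses.replace(registry, profiles=profiles)


def test_degenerate_mc_equals_point_oracle(registry):
    """All-point parameters + fixed concentrations reproduce the
    deterministic risk result in every iteration, exactly."""
    cfg = MCConfig(seed=3, n_iterations=200, concentration_mode="fixed",
                   groups=("rural",), populations=("adults", "children"))
    res = run_mc(cfg, _pointify(registry))
    for pop in ("adults", "children"):
        oracle = assess_point_risk(RURAL, pop, registry)
        df = res.frame(pop, "rural")
        assert np.array_equal(df["TCR"], np.full(200, oracle.tcr))
        assert np.array_equal(df["THI"], np.full(200, oracle.thi))
        for m, hq in oracle.hq.items():
            assert np.array_equal(df[f"HQ_{m}"], np.full(200, hq))


def test_rowwise_conservation_is_exact(registry):
    cfg = MCConfig(seed=9, n_iterations=2000)
    res = run_mc(cfg, registry)
    for (pop, group), df in res.frames.items():
        hq_cols = [c for c in df.columns if c.startswith("HQ_")]
        cr_cols = [c for c in df.columns if c.startswith("CR_")]
        assert np.array_equal(df["THI"].to_numpy(),
                              np.sum([df[c].to_numpy() for c in hq_cols], axis=0))
        assert np.array_equal(df["TCR"].to_numpy(),
                              np.sum([df[c].to_numpy() for c in cr_cols], axis=0))


def test_identical_config_reproduces_draws_bit_for_bit(registry):
    cfg = MCConfig(seed=42, n_iterations=500)
    a, b = run_mc(cfg, registry), run_mc(cfg, registry)
    for key in a.frames:
        pd.testing.assert_frame_equal(a.frames[key], b.frames[key])


def test_adding_a_group_does_not_perturb_another(registry):
    both = run_mc(MCConfig(seed=5, n_iterations=500), registry)
    urban_only = run_mc(MCConfig(seed=5, n_iterations=500, groups=("urban",)), registry)
    pd.testing.assert_frame_equal(both.frame("adults", "urban"),
                                  urban_only.frame("adults", "urban"))


def test_ef_only_variation_matches_analytic_mean(registry):
    """With only EF sampled (triangular), TCR is linear in EF, so its MC
    mean must equal point TCR x (analytic EF mean / 350) up to 3 SE."""
    n = 10_000
    cfg = MCConfig(seed=17, n_iterations=n, concentration_mode="fixed",
                   groups=("rural",), populations=("adults",))
    res = run_mc(cfg, _pointify(registry, keep=("ef",)))
    draws = res.frame("adults", "rural")["TCR"].to_numpy()
    point = assess_point_risk(RURAL, "adults", registry).tcr
    analytic = point * ((180 + 350 + 360) / 3) / 350
    se = draws.std(ddof=1) / np.sqrt(n)
    assert abs(draws.mean() - analytic) < 3 * se


def test_distribution_mode_mean_matches_linearity_prediction(registry):
    """TCR is linear in concentration and in each sampled parameter, so the
    full distribution-mode MC mean sits at point TCR x (EF mean / EF mode)
    up to detection-limit truncation (<1 %) and sampling error; with EF
    fixed at its mode it returns to the point estimate itself."""
    point = assess_point_risk(RURAL, "adults", registry).tcr
    cfg = MCConfig(seed=23, n_iterations=10_000, groups=("rural",), populations=("adults",))
    res = run_mc(cfg, registry)
    predicted = point * ((180 + 350 + 360) / 3) / 350
    assert res.frame("adults", "rural")["TCR"].mean() == pytest.approx(predicted, rel=0.02)
    res_fix = run_mc(dataclasses.replace(cfg, fix_ef=True), registry)
    assert res_fix.frame("adults", "rural")["TCR"].mean() == pytest.approx(point, rel=0.02)


def test_percentile_monotonicity(registry):
    res = run_mc(MCConfig(seed=31, n_iterations=2000), registry)
    s = res.summary()
    for _, row in s.iterrows():
        assert row["p5"] <= row["p25"] <= row["p50"] <= row["p75"] <= row["p95"]


def test_summary_covers_all_combinations(registry):
    res = run_mc(MCConfig(seed=1, n_iterations=200), registry)
    s = res.summary()
    assert set(zip(s["population"], s["group"])) == {
        (p, g) for p in ("children", "adults") for g in ("urban", "rural")
    }
    assert {"THI", "TCR"} <= set(s["output"])


def test_exceedance_probability_enumeration():
    assert exceedance_probability([0.5, 1.5, 2.5, 3.5], 1.0) == 0.75
    assert exceedance_probability([0.1, 0.2], 1.0) == 0.0
    assert cumulative_frequency([0.5, 1.5, 2.5, 3.5], 1.5) == 0.5


def test_exceedance_probability_standard_normal(rng):
    draws = rng.normal(size=10_000)
    se = 0.5 / np.sqrt(10_000)
    assert abs(exceedance_probability(draws, 0.0) - 0.5) < 3 * se


def test_sample_realization_statistics(registry, rng):
    n = 100_000
    real = sample_realization(registry.profile("adults"), rng, n)
    assert abs(real.ir.mean() - 1.95) < 3 * 0.3 / np.sqrt(n)
    assert real.ir.std(ddof=1) == pytest.approx(0.3, rel=0.05)
    tri_mean = (180 + 350 + 360) / 3
    tri_sd = np.sqrt((180**2 + 350**2 + 360**2 - 180 * 350 - 180 * 360 - 350 * 360) / 18)
    assert abs(real.ef.mean() - tri_mean) < 3 * tri_sd / np.sqrt(n)
    assert (real.ef <= 366).all() and (real.ir > 0).all() and (real.bw > 0).all()


def test_sample_realization_degenerate_profile(registry, rng):
    prof = _pointify(registry).profile("children")
    real = sample_realization(prof, rng, 50)
    assert np.unique(real.ir).size == 1 and np.unique(real.ef).size == 1


def test_fix_ef_holds_mode(registry, rng):
    real = sample_realization(registry.profile("adults"), rng, 100, fix_ef=True)
    assert np.array_equal(real.ef, np.full(100, 350.0))


def test_empirical_mode_resamples_rows(registry, toy_samples):
    toy_samples["group"] = "rural"
    cfg = MCConfig(seed=2, n_iterations=500, concentration_mode="empirical",
                   groups=("rural",), populations=("adults",))
    res = run_mc(cfg, registry, samples=toy_samples)
    hg = res.frame("adults", "rural")["conc_Hg"].to_numpy()
    assert set(np.unique(hg)) <= {0.10, 0.40}
    # joint resampling preserves inter-metal correlation: Hg 0.10 rows
    # always carry As 2.5
    as_ = res.frame("adults", "rural")["conc_As"].to_numpy()
    assert np.array_equal(hg == 0.10, as_ == 2.5)


def test_config_validation(registry):
    with pytest.raises(ValueError):
        MCConfig(seed=None)
    with pytest.raises(ValueError):
        MCConfig(seed=1, n_iterations=50)
    with pytest.raises(ValueError):
        MCConfig(seed=1, concentration_mode="bootstrap")
    with pytest.raises(ValueError):
        run_mc(MCConfig(seed=1, n_iterations=100, concentration_mode="empirical"),
               registry, samples=None, group_profiles={})
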