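"""Monte Carlo propagation of exposure and concentration uncertainty.

Each iteration draws one exposure-parameter realization per population
(intake rate and body weight from their normal specs, exposure frequency
from the triangular spec; duration, skin area, event time and frequency
stay at their point values) and one concentration vector per group, then
evaluates the full dose→risk chain, yielding joint draws of every
per-metal HQ and CR plus THI and TCR.  Summaries (means, percentiles,
exceedance probabilities) are always computed from the raw draws.

Concentration modes
-------------------
``distribution``
    Per-metal lognormal fitted to the group's mean/SD by moment matching,
    truncated at the detection limit (the default; the survey's raw data
    are unpublished, so a fitted distribution is the only reproducible
    choice).
``empirical``
    Joint resampling of provided sample rows, preserving inter-metal
    correlation.
``fixed``
    Group-mean concentrations held constant; only exposure parameters vary.

Reproducibility
---------------
A single integer seed drives everything.  Sub-streams are derived
deterministically per population and per group (keyed by fixed indices,
not request order), so adding a group to a run never perturbs another
group's draws, and identical configurations reproduce draws bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .exposure import ParameterRealization, cdi_dermal, cdi_ingestion
from .registry import METALS, ExposureProfile, Registry, default_registry
from .risk import cancer_risk, hazard_quotient
from .synthetic import GroupProfile, fit_lognormal_moments

__all__ = [
    "MCConfig",
    "MCResult",
    "sample_realization",
    "run_mc",
    "exceedance_probability",
    "cumulative_frequency",
]

_PERCENTILES = (1, 5, 25, 50, 75, 95, 99)
_POP_INDEX = {"children": 0, "adults": 1}
_GROUP_INDEX = {"urban": 0, "rural": 1}


@dataclass(frozen=True)
class MCConfig:
    """Configuration of one Monte Carlo run."""

    seed: int
    n_iterations: int = 10_000
    concentration_mode: str = "distribution"
    populations: tuple[str, ...] = ("children", "adults")
    groups: tuple[str, ...] = ("urban", "rural")
    fix_ef: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("MCConfig requires an explicit seed")
        if self.n_iterations < 100:
            raise ValueError(f"n_iterations must be >= 100, got {self.n_iterations}")
        if self.concentration_mode not in ("distribution", "empirical", "fixed"):
            raise ValueError(
                f"unknown concentration_mode {self.concentration_mode!r}"
            )
        if not self.populations or not self.groups:
            raise ValueError("at least one population and one group are required")


def _substream(seed: int, kind: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(kind, index)))


def sample_realization(
    profile: ExposureProfile,
    rng: np.random.Generator,
    n: int = 1,
    endpoint: str = "noncancer",
    fix_ef: bool = False,
) -> ParameterRealization:
    """Draw ``n`` joint exposure-parameter realizations for one population.

    IR and BW come from their (truncated) specs, EF from its triangular
    spec — or held at its most probable value when ``fix_ef`` — and the
    remaining parameters are fixed.  The returned realization carries
    arrays, ready for vectorised dose evaluation.
    """
    at = profile.at_noncancer if endpoint == "noncancer" else profile.at_cancer
    ir = profile.ir.sample(rng, n)
    ef = (
        np.full(n, profile.ef.point_value())
        if fix_ef
        else profile.ef.sample(rng, n)
    )
    bw = profile.bw.sample(rng, n)
    return ParameterRealization(
        population=profile.population,
        ir=ir,
        ef=ef,
        ed=profile.ed,
        bw=bw,
        at=at,
        sa=profile.sa,
        t_event=profile.t_event,
        ev=profile.ev,
    )


def _concentration_draws(
    config: MCConfig,
    group: str,
    rng: np.random.Generator,
    registry: Registry,
    samples: pd.DataFrame | None,
    profiles: Mapping[str, GroupProfile] | None,
) -> dict[str, np.ndarray]:
    n = config.n_iterations
    metals = [m for m in METALS if m in registry.metals]
    mode = config.concentration_mode

    if mode == "empirical":
        if samples is None:
            raise ValueError("empirical concentration mode requires a sample table")
        gdf = samples[samples["group"] == group]
        if gdf.empty:
            raise ValueError(f"no samples for group {group!r}")
        idx = rng.integers(0, len(gdf), n)
        return {m: gdf[m].to_numpy(dtype=float)[idx] for m in metals}

    # moments either from provided samples or from group profiles
    if samples is not None:
        gdf = samples[samples["group"] == group]
        if gdf.empty:
            raise ValueError(f"no samples for group {group!r}")
        moments = {
            m: (float(gdf[m].mean()), float(gdf[m].std(ddof=1))) for m in metals
        }
    elif profiles is not None:
        prof = profiles[group]
        moments = {
            m: (prof.metals[m].target_mean, prof.metals[m].target_sd)
            for m in metals
            if m in prof.metals
        }
    else:
        raise ValueError("need either a sample table or group profiles")

    if mode == "fixed":
        return {m: np.full(n, mean) for m, (mean, _) in moments.items()}

    draws = {}
    for m, (mean, sd) in moments.items():
        spec = fit_lognormal_moments(mean, sd)
        spec = DistributionSpec(
            spec.family, spec.params, lower_trunc=registry.metal(m).detection_limit
        )
        draws[m] = spec.sample(rng, n)
    return draws


@dataclass(frozen=True)
class MCResult:
    """Draw matrices and metadata of one Monte Carlo run.

    ``frames[(population, group)]`` holds one row per iteration with input
    columns (``IR``, ``EF``, ``BW``, ``conc_<metal>``) and output columns
    (``HQ_<metal>``, ``CR_<metal>``, ``THI``, ``TCR``).
    """

    config: MCConfig
    frames: dict[tuple[str, str], pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def frame(self, population: str, group: str) -> pd.DataFrame:
        return self.frames[(population, group)]

    def output_columns(self) -> list[str]:
        any_frame = next(iter(self.frames.values()))
        return [
            c for c in any_frame.columns
            if c.startswith(("HQ_", "CR_")) or c in ("THI", "TCR")
        ]

    def summary(self) -> pd.DataFrame:
        """Mean, SD and percentiles of every output, from raw draws."""
        rows = []
        for (pop, group), df in self.frames.items():
            for col in self.output_columns():
                x = df[col].to_numpy()
                row = {
                    "population": pop,
                    "group": group,
                    "output": col,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                }
                for p, v in zip(_PERCENTILES, np.percentile(x, _PERCENTILES)):
                    row[f"p{p}"] = v
                rows.append(row)
        return pd.DataFrame(rows)

    def exceedance(self, population: str, group: str, output: str, threshold: float) -> float:
        return exceedance_probability(self.frame(population, group)[output], threshold)


def run_mc(
    config: MCConfig,
    registry: Registry | None = None,
    samples: pd.DataFrame | None = None,
    group_profiles: Mapping[str, GroupProfile] | None = None,
) -> MCResult:
    """Execute a Monte Carlo run and return all draws.

    Concentration inputs come from ``samples`` (a standard sample table)
    when given, otherwise from ``group_profiles``; with neither, the
    survey's published group summary statistics are used.
    """
    reg = registry if registry is not None else default_registry()
    if samples is None and group_profiles is None:
        from . import survey

        group_profiles = {g: survey.group_profile(g) for g in config.groups}

    n = config.n_iterations
    metals = [m for m in METALS if m in reg.metals]

    # parameter draws: one joint (IR, EF, BW) stream per population
    params: dict[str, dict[str, np.ndarray]] = {}
    for pop in config.populations:
        profile = reg.profile(pop)
        idx = _POP_INDEX.get(pop)
        if idx is None:
            idx = 10 + sorted(set(config.populations) - set(_POP_INDEX)).index(pop)
        rng = _substream(config.seed, 0, idx)
        real = sample_realization(profile, rng, n, "noncancer", config.fix_ef)
        params[pop] = {"IR": real.ir, "EF": real.ef, "BW": real.bw}

    # concentration draws: one stream per group, shared across populations
    concs: dict[str, dict[str, np.ndarray]] = {}
    for group in config.groups:
        idx = _GROUP_INDEX.get(group)
        if idx is None:
            idx = 10 + sorted(set(config.groups) - set(_GROUP_INDEX)).index(group)
        rng = _substream(config.seed, 1, idx)
        concs[group] = _concentration_draws(config, group, rng, reg, samples, group_profiles)

    frames: dict[tuple[str, str], pd.DataFrame] = {}
    for pop in config.populations:
        profile = reg.profile(pop)
        p = params[pop]
        base = dict(
            population=profile.population,
            ir=p["IR"], ef=p["EF"], bw=p["BW"],
            ed=profile.ed, sa=profile.sa, t_event=profile.t_event, ev=profile.ev,
        )
        r_nc = ParameterRealization(at=profile.at_noncancer, **base)
        r_ca = ParameterRealization(at=profile.at_cancer, **base)
        for group in config.groups:
            cols: dict[str, np.ndarray] = {"IR": p["IR"], "EF": p["EF"], "BW": p["BW"]}
            hq_cols, cr_cols = [], []
            for m in metals:
                if m not in concs[group]:
                    continue
                c = concs[group][m]
                cols[f"conc_{m}"] = c
                metal = reg.metal(m)
                if metal.noncarcinogenic_assessable:
                    cols[f"HQ_{m}"] = hazard_quotient(
                        cdi_ingestion(c, r_nc), cdi_dermal(c, metal.kp, r_nc),
                        metal.rfd_ing, metal.rfd_derm,
                    )
                    hq_cols.append(f"HQ_{m}")
                if metal.carcinogenic_assessable:
                    cols[f"CR_{m}"] = cancer_risk(
                        cdi_ingestion(c, r_ca), cdi_dermal(c, metal.kp, r_ca),
                        metal.sf_ing, metal.sf_derm,
                    )
                    cr_cols.append(f"CR_{m}")
            if hq_cols:
                cols["THI"] = np.sum([cols[c] for c in hq_cols], axis=0)
            if cr_cols:
                cols["TCR"] = np.sum([cols[c] for c in cr_cols], axis=0)
            frames[(pop, group)] = pd.DataFrame(cols)

    metadata = {
        "seed": config.seed,
        "n_iterations": n,
        "concentration_mode": config.concentration_mode,
        "fix_ef": config.fix_ef,
        "populations": list(config.populations),
        "groups": list(config.groups),
    }
    return MCResult(config=config, frames=frames, metadata=metadata)


def exceedance_probability(draws, threshold: float) -> float:
    """Fraction of draws strictly greater than ``threshold``."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("exceedance_probability requires at least one draw")
    return float((x > threshold).mean())


def cumulative_frequency(draws, value: float) -> float:
    """Fraction of draws at or below ``value`` (the empirical CDF)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("cumulative_frequency requires at least one draw")
    return float((x <= value).mean())
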