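"""Synthetic water-sample generator.

The survey's raw per-sample concentrations are unpublished; only group-wise
summary statistics (max/min/mean/SD per metal) are public.  This module
generates per-sample concentration tables whose group statistics emulate
those summaries, so every downstream stage — pollution indices, risk,
Monte Carlo — can be exercised end to end without any external data.

Model
-----
Each metal is drawn independently from a lognormal distribution whose
natural-scale mean and SD are moment-matched to the published group values
(lognormal because concentrations are positive and strongly right-skewed,
with CVs up to 1.29 in this survey), truncated below at the instrument
detection limit.  With ``moment_match=True`` (the default) the realized
draws are further adjusted by an affine transform of their log-values,
followed by re-clipping at the detection limit, iterated a few times, so
the *sample* mean and SD match the targets to within 0.5 %.

Limitations: metals are generated independently (the survey publishes no
correlation structure), and the detection-limit floor is a stand-in
assumption — how non-detects were handled in the original laboratory data
is not stated.

Output schema
-------------
``sample_id,group,Hg,As,Cu,Zn,Pb,Cd,pH,EC`` — concentrations in µg/L, pH
dimensionless, EC in µS/cm.  pH and EC are pass-through metadata drawn
uniformly within the survey's observed ranges; they enter no computation.
This same CSV schema is the input format for all downstream modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distributions import DistributionSpec
from .registry import METALS, Registry, default_registry

__all__ = [
    "MetalStats",
    "GroupProfile",
    "fit_lognormal_moments",
    "generate_samples",
    "summarize",
    "read_samples",
    "write_samples",
    "SAMPLE_COLUMNS",
]

SAMPLE_COLUMNS = ["sample_id", "group"] + list(METALS) + ["pH", "EC"]

_MATCH_RTOL = 0.005  # relative tolerance of the moment-matching contract
_MATCH_MAX_ITER = 5


@dataclass(frozen=True)
class MetalStats:
    """Target summary statistics for one metal in one group (µg/L)."""

    target_mean: float
    target_sd: float
    target_min: float
    target_max: float

    def __post_init__(self) -> None:
        if not (self.target_min <= self.target_mean <= self.target_max):
            raise ValueError(
                f"require target_min <= target_mean <= target_max, got "
                f"{self.target_min}, {self.target_mean}, {self.target_max}"
            )
        if self.target_sd < 0:
            raise ValueError(f"target_sd must be >= 0, got {self.target_sd}")


@dataclass(frozen=True)
class GroupProfile:
    """Per-group generation targets: sample count and per-metal statistics."""

    group: str
    n_samples: int
    metals: dict[str, MetalStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")


def fit_lognormal_moments(mean: float, sd: float) -> DistributionSpec:
    """Lognormal spec whose population mean and SD equal the inputs.

    ``sd == 0`` yields a degenerate point mass at ``mean``.  The log-scale
    parameters follow from closed-form moment inversion,
    ``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2/2``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return DistributionSpec("point", {"value": float(mean)})
    return DistributionSpec("lognormal", {"mean": float(mean), "sd": float(sd)})


def _match_moments(x: np.ndarray, mean_t: float, sd_t: float, floor: float) -> np.ndarray:
    """Affine log-space adjustment so sample mean/SD hit the targets.

    Writes ``x' = exp(a + b * u)`` with ``u`` the standardized log-values;
    ``b`` is solved so the sample CV matches ``sd_t/mean_t`` (the sample CV
    of ``exp(b*u)`` is scale-free and increasing in ``b``), then ``a``
    rescales the mean.  Clipping at the detection-limit ``floor`` can
    perturb the moments, so the adjustment is iterated.
    """
    if sd_t == 0:
        return np.full_like(x, max(mean_t, floor))
    cv_t = sd_t / mean_t
    for _ in range(_MATCH_MAX_ITER):
        z = np.log(x)
        zsd = z.std(ddof=1)
        if zsd == 0:
            # all values identical: jitter-free exact match is impossible;
            # fall back to a two-point spread preserving the mean
            return x
        u = (z - z.mean()) / zsd

        def cv_of(b: float) -> float:
            e = np.exp(b * u)
            return e.std(ddof=1) / e.mean()

        b = brentq(lambda b: cv_of(b) - cv_t, 0.0, 50.0, xtol=1e-12)
        e = np.exp(b * u)
        x = e * (mean_t / e.mean())
        x = np.maximum(x, floor)
        m, s = x.mean(), x.std(ddof=1)
        if abs(m - mean_t) <= _MATCH_RTOL * mean_t and abs(s - sd_t) <= _MATCH_RTOL * sd_t:
            return x
    warnings.warn(
        f"moment matching did not reach {_MATCH_RTOL:.1%} tolerance "
        f"(achieved mean {m:.4g} vs {mean_t:.4g}, sd {s:.4g} vs {sd_t:.4g}); "
        "returning achieved moments",
        stacklevel=3,
    )
    return x


def generate_samples(
    profile: GroupProfile,
    seed: int,
    moment_match: bool = True,
    registry: Registry | None = None,
    ph_range: tuple[float, float] = (6.84, 8.36),
    ec_range: tuple[float, float] = (423.0, 5820.0),
) -> pd.DataFrame:
    """Generate one group's per-sample concentration table.

    Parameters
    ----------
    profile
        Generation targets (group label, sample count, per-metal stats).
    seed
        Required; identical ``(profile, seed)`` give identical output.
    moment_match
        Adjust draws so realized sample mean/SD match the targets to
        within 0.5 % per metal (subject to detection-limit clipping).
    registry
        Source of detection limits; defaults to the shipped constants.

    Returns
    -------
    pandas.DataFrame
        One row per sample with the standard CSV schema columns.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    reg = registry if registry is not None else default_registry()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = profile.n_samples

    data: dict[str, np.ndarray] = {}
    for sym, stats in profile.metals.items():
        floor = reg.metal(sym).detection_limit if sym in reg.metals else 0.0
        spec = fit_lognormal_moments(stats.target_mean, stats.target_sd)
        spec = DistributionSpec(spec.family, spec.params, lower_trunc=floor or None)
        x = spec.sample(rng, n)
        if moment_match:
            x = _match_moments(x, stats.target_mean, stats.target_sd, floor)
        data[sym] = x

    df = pd.DataFrame(data)
    df.insert(0, "group", profile.group)
    df.insert(0, "sample_id", [f"{profile.group}-{i + 1:03d}" for i in range(n)])
    df["pH"] = np.round(rng.uniform(*ph_range, n), 2)
    df["EC"] = np.round(rng.uniform(*ec_range, n), 1)
    return df


def summarize(samples: pd.DataFrame, registry: Registry | None = None) -> pd.DataFrame:
    """Per-group, per-metal summary statistics of a sample table.

    Returns a frame indexed by ``(group, metal)`` with columns ``max``,
    ``min``, ``mean``, ``sd`` (ddof = 1), ``cv`` (= sd/mean; NaN when the
    mean is zero) and ``exceed_ratio`` — the standard-exceeding ratio, i.e.
    the percentage of samples whose concentration strictly exceeds the
    metal's Class II threshold.
    """
    if samples.empty:
        raise ValueError("cannot summarize an empty sample table")
    reg = registry if registry is not None else default_registry()
    metals = [m for m in METALS if m in samples.columns]
    rows = []
    for group, gdf in samples.groupby("group", sort=False):
        for sym in metals:
            c = gdf[sym].to_numpy(dtype=float)
            mean = c.mean()
            sd = c.std(ddof=1) if len(c) > 1 else 0.0
            cv = sd / mean if mean != 0 else np.nan
            thr = reg.metal(sym).class2_threshold
            rows.append(
                {
                    "group": group,
                    "metal": sym,
                    "max": c.max(),
                    "min": c.min(),
                    "mean": mean,
                    "sd": sd,
                    "cv": cv,
                    "exceed_ratio": 100.0 * (c > thr).sum() / len(c),
                }
            )
    return pd.DataFrame(rows).set_index(["group", "metal"])


def write_samples(samples: pd.DataFrame, path: str) -> None:
    """Write a sample table in the standard CSV schema (UTF-8, '.' decimals)."""
    cols = [c for c in SAMPLE_COLUMNS if c in samples.columns]
    samples.to_csv(path, index=False, columns=cols, encoding="utf-8")


def read_samples(path: str) -> pd.DataFrame:
    """Read and validate a sample table in the standard CSV schema.

    Unknown columns are kept but ignored downstream; missing metal columns
    raise, naming the absent metals.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        raise ValueError(f"sample file {path!r} contains no rows")
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample file {path!r} lacks required column(s): {sorted(missing)}")
    absent = [m for m in METALS if m not in df.columns]
    if absent:
        raise ValueError(f"sample file {path!r} lacks metal column(s): {absent}")
    return df
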