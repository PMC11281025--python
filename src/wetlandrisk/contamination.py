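"""Single-factor and Nemerow composite pollution indices.

The single-factor index of metal *i* is ``P_i = C_i / S_i`` with ``C_i``
the concentration and ``S_i`` the Class II threshold of the surface-water
quality standard (both µg/L).  The Nemerow pollution index combines the
worst and the average single-factor index,

    NPI = sqrt((P_max² + P_ave²) / 2),

emphasizing the dominant pollutant while still reflecting the overall
burden.  Contamination classes attach through the registry's ``Pi`` and
``NPI`` schemes (no / slight / light / moderate / high contamination at
cut points 0.7, 1, 2, 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import METALS, Registry, default_registry

__all__ = [
    "single_pollution_index",
    "nemerow_index",
    "ContaminationResult",
    "assess_contamination",
]


def single_pollution_index(c: float, s: float) -> float:
    """``P_i = c / s``: concentration over its regulatory threshold.

    Both in µg/L; ``c`` must be nonnegative, ``s`` strictly positive.
    """
    if s <= 0:
        raise ValueError(f"threshold must be strictly positive, got {s}")
    if c < 0:
        raise ValueError(f"concentration must be nonnegative, got {c}")
    return c / s


def nemerow_index(p: Sequence[float] | Mapping[str, float]) -> float:
    """Nemerow composite index of a vector of single-factor indices."""
    values = np.asarray(list(p.values()) if isinstance(p, Mapping) else p, dtype=float)
    if values.size == 0:
        raise ValueError("nemerow_index requires at least one single-factor index")
    if (values < 0).any():
        raise ValueError("single-factor indices must be nonnegative")
    p_max = values.max()
    p_ave = values.mean()
    return float(np.sqrt((p_max**2 + p_ave**2) / 2.0))


@dataclass(frozen=True)
class ContaminationResult:
    """Pollution indices and classes for one sample or one group."""

    scope: str  # sample id or group label
    p_i: dict[str, float]
    npi: float
    p_class: dict[str, str]
    npi_class: str

    @property
    def p_max(self) -> float:
        return max(self.p_i.values())

    @property
    def p_ave(self) -> float:
        return float(np.mean(list(self.p_i.values())))


def _assess_one(scope: str, conc: Mapping[str, float], reg: Registry,
                metals: Iterable[str]) -> ContaminationResult:
    pi_scheme = reg.scheme("Pi")
    npi_scheme = reg.scheme("NPI")
    p_i = {m: single_pollution_index(conc[m], reg.metal(m).class2_threshold) for m in metals}
    npi = nemerow_index(p_i)
    return ContaminationResult(
        scope=scope,
        p_i=p_i,
        npi=npi,
        p_class={m: pi_scheme.classify(v) for m, v in p_i.items()},
        npi_class=npi_scheme.classify(npi),
    )


def assess_contamination(
    samples: pd.DataFrame,
    registry: Registry | None = None,
) -> tuple[list[ContaminationResult], list[ContaminationResult]]:
    """Indices per sample and per group for a standard sample table.

    Group-level indices are computed from the group-mean concentrations
    (the reading under which the published group averages are recovered
    exactly from the per-metal average indices); per-sample results give
    the distributional view.  Returns ``(per_sample, per_group)``.

    Raises if any metal column is missing, naming sample and metal.
    """
    reg = registry if registry is not None else default_registry()
    metals = [m for m in METALS if m in reg.metals]
    missing = [m for m in metals if m not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks metal column(s): {missing}")

    per_sample = []
    for _, row in samples.iterrows():
        conc = {m: row[m] for m in metals}
        bad = [m for m, v in conc.items() if pd.isna(v)]
        if bad:
            raise ValueError(f"sample {row['sample_id']!r}: missing concentration for {bad}")
        per_sample.append(_assess_one(str(row["sample_id"]), conc, reg, metals))

    per_group = []
    for group, gdf in samples.groupby("group", sort=False):
        means = {m: float(gdf[m].mean()) for m in metals}
        per_group.append(_assess_one(str(group), means, reg, metals))
    return per_sample, per_group


def results_to_frames(
    results: Iterable[ContaminationResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy frames ``(scope, metal, P_i, class)`` and ``(scope, NPI, class)``."""
    pi_rows, npi_rows = [], []
    for r in results:
        for m, v in r.p_i.items():
            pi_rows.append({"scope": r.scope, "metal": m, "P_i": v, "class": r.p_class[m]})
        npi_rows.append({"scope": r.scope, "NPI": r.npi, "class": r.npi_class})
    return pd.DataFrame(pi_rows), pd.DataFrame(npi_rows)
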