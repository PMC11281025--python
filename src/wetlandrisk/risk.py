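"""Non-carcinogenic and carcinogenic risk aggregation.

Per metal and route the chronic daily intakes convert to:

hazard quotient (non-carcinogenic)::

    HQ = CDI_ing / RfD_ing + CDI_derm / RfD_derm        THI = Σ HQ

cancer risk (carcinogenic)::

    CR = CDI_ing · SF_ing + CDI_derm · SF_derm          TCR = Σ CR

HQ (or THI) above 1 flags a potential non-carcinogenic risk; CR/TCR
classify from "very low" (< 1e-6) to "extremely high" (> 0.1).

Only metals with both reference doses enter THI, and only metals with both
slope factors (As and Cd here) enter TCR; metals lacking toxicity values
for a pathway are skipped, never imputed, and the result records which
were skipped.

All operations are vectorised: passing Monte Carlo draw arrays for the
CDIs yields draw arrays for HQ/CR, so the same code backs point-estimate
and probabilistic assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exposure import cdi_dermal, cdi_ingestion, point_realization
from .registry import METALS, Registry, default_registry

__all__ = [
    "hazard_quotient",
    "total_hazard_index",
    "cancer_risk",
    "total_cancer_risk",
    "contribution_shares",
    "RiskResult",
    "assess_point_risk",
]


def hazard_quotient(cdi_ing, cdi_derm, rfd_ing: float, rfd_derm: float):
    """Sum of the two route intake/reference-dose ratios."""
    if rfd_ing <= 0 or rfd_derm <= 0:
        raise ValueError("reference doses must be strictly positive")
    return cdi_ing / rfd_ing + cdi_derm / rfd_derm


def total_hazard_index(hqs: Mapping[str, float] | Sequence[float]):
    """Arithmetic sum of per-metal hazard quotients."""
    values = list(hqs.values()) if isinstance(hqs, Mapping) else list(hqs)
    if not values:
        raise ValueError("total_hazard_index requires at least one hazard quotient")
    return np.sum(values, axis=0)


def cancer_risk(cdi_ing, cdi_derm, sf_ing: float, sf_derm: float):
    """Slope-factor-weighted sum of the two route intakes."""
    if sf_ing is None or sf_derm is None or sf_ing <= 0 or sf_derm <= 0:
        raise ValueError(
            "cancer_risk requires both slope factors; metals without them "
            "are not carcinogenic-assessable and must be excluded upstream"
        )
    return cdi_ing * sf_ing + cdi_derm * sf_derm


def total_cancer_risk(crs: Mapping[str, float] | Sequence[float]):
    """Arithmetic sum of per-metal cancer risks."""
    values = list(crs.values()) if isinstance(crs, Mapping) else list(crs)
    if not values:
        raise ValueError("total_cancer_risk requires at least one cancer risk")
    return np.sum(values, axis=0)


def contribution_shares(values: Mapping[str, float]) -> dict[str, float] | None:
    """Percentage share of each entry in the total; ``None`` if total is 0."""
    total = float(sum(values.values()))
    if total == 0:
        return None
    if total < 0 or any(v < 0 for v in values.values()):
        raise ValueError("contribution shares require nonnegative values")
    return {k: 100.0 * v / total for k, v in values.items()}


@dataclass(frozen=True)
class RiskResult:
    """Point-estimate risk for one population and one concentration set."""

    population: str
    hq: dict[str, float]
    thi: float
    cr: dict[str, float]
    tcr: float | None
    thi_flag: str
    tcr_class: str | None
    hq_shares: dict[str, float] | None
    cr_shares: dict[str, float] | None
    skipped_noncancer: tuple[str, ...] = field(default_factory=tuple)
    skipped_cancer: tuple[str, ...] = field(default_factory=tuple)


def assess_point_risk(
    concentrations: Mapping[str, float],
    population: str,
    registry: Registry | None = None,
) -> RiskResult:
    """Deterministic risk for one concentration vector and population.

    Every distribution spec collapses to its point value (mean for normal
    parameters, the most probable value for the triangular exposure
    frequency).  This is the package's reference evaluation mode: the
    degenerate Monte Carlo run must reproduce it exactly.
    """
    reg = registry if registry is not None else default_registry()
    profile = reg.profile(population)
    r_nc = point_realization(profile, "noncancer")
    r_ca = point_realization(profile, "cancer")

    metals = [m for m in METALS if m in reg.metals and m in concentrations]
    hq: dict[str, float] = {}
    cr: dict[str, float] = {}
    skipped_nc, skipped_ca = [], []
    for sym in metals:
        metal = reg.metal(sym)
        c = float(concentrations[sym])
        if metal.noncarcinogenic_assessable:
            hq[sym] = hazard_quotient(
                cdi_ingestion(c, r_nc),
                cdi_dermal(c, metal.kp, r_nc),
                metal.rfd_ing,
                metal.rfd_derm,
            )
        else:
            skipped_nc.append(sym)
        if metal.carcinogenic_assessable:
            cr[sym] = cancer_risk(
                cdi_ingestion(c, r_ca),
                cdi_dermal(c, metal.kp, r_ca),
                metal.sf_ing,
                metal.sf_derm,
            )
        else:
            skipped_ca.append(sym)

    thi = float(total_hazard_index(hq)) if hq else 0.0
    tcr = float(total_cancer_risk(cr)) if cr else None
    hq_scheme = reg.scheme("HQ")
    cr_scheme = reg.scheme("CR")
    return RiskResult(
        population=population,
        hq=hq,
        thi=thi,
        cr=cr,
        tcr=tcr,
        thi_flag=hq_scheme.classify(thi),
        tcr_class=cr_scheme.classify(tcr) if tcr is not None else None,
        hq_shares=contribution_shares(hq) if hq else None,
        cr_shares=contribution_shares(cr) if cr else None,
        skipped_noncancer=tuple(skipped_nc),
        skipped_cancer=tuple(skipped_ca),
    )
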