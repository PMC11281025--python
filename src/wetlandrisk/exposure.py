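"""Chronic daily intake (CDI) for the ingestion and dermal routes.

The dose equations follow the US EPA exposure framework.  For water
concentration ``C`` (µg/L) and a parameter realization ``r``:

ingestion (µg/kg/d)::

    CDI_ing = C · IR · EF · ED / (BW · AT)

dermal contact (µg/kg/d)::

    CDI_derm = C · SA · Kp · T_event · EV · EF · ED · 10⁻³ / (BW · AT)

where the 10⁻³ converts the absorbed water volume (cm³, since SA·Kp·T is
cm²·cm/h·h) to litres.  The averaging time ``AT`` is chosen by endpoint —
non-cancer or cancer — not by population; callers select it before
building the realization, so both functions stay pure.

All functions are NumPy-vectorised: scalar or array inputs broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registry import ExposureProfile

__all__ = ["ParameterRealization", "cdi_ingestion", "cdi_dermal", "point_realization"]

ArrayLike = "float | np.ndarray"


@dataclass(frozen=True)
class ParameterRealization:
    """One concrete set of exposure parameter values.

    ``ir`` L/day, ``ef`` days/year, ``ed`` years, ``bw`` kg, ``at`` days
    (already endpoint-appropriate), ``sa`` cm², ``t_event`` h/event,
    ``ev`` events/day.  Fields may be arrays of a common length for
    vectorised Monte Carlo evaluation.
    """

    population: str
    ir: "float | np.ndarray"
    ef: "float | np.ndarray"
    ed: float
    bw: "float | np.ndarray"
    at: float
    sa: float
    t_event: float
    ev: float

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "at", "sa", "t_event", "ev"):
            v = np.asarray(getattr(self, name))
            if not (v > 0).all():
                raise ValueError(f"ParameterRealization field {name!r} must be strictly positive")
        if not (np.asarray(self.ef) <= 366).all():
            raise ValueError("exposure frequency cannot exceed 366 days/year")


def point_realization(profile: ExposureProfile, endpoint: str) -> ParameterRealization:
    """Collapse a profile to its point-estimate realization.

    Distribution specs collapse by the point convention (mean for normal,
    mode for triangular); ``endpoint`` is ``"noncancer"`` or ``"cancer"``
    and selects the averaging time.
    """
    if endpoint not in ("noncancer", "cancer"):
        raise ValueError(f"endpoint must be 'noncancer' or 'cancer', got {endpoint!r}")
    at = profile.at_noncancer if endpoint == "noncancer" else profile.at_cancer
    return ParameterRealization(
        population=profile.population,
        ir=profile.ir.point_value(),
        ef=profile.ef.point_value(),
        ed=profile.ed,
        bw=profile.bw.point_value(),
        at=at,
        sa=profile.sa,
        t_event=profile.t_event,
        ev=profile.ev,
    )


def cdi_ingestion(c, r: ParameterRealization):
    """Ingestion-route chronic daily intake, µg/kg/d (linear in ``c``)."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be nonnegative")
    out = c * r.ir * r.ef * r.ed / (r.bw * r.at)
    return float(out) if out.ndim == 0 and np.isscalar(r.ir) else out


def cdi_dermal(c, kp: float, r: ParameterRealization):
    """Dermal-route chronic daily intake, µg/kg/d (linear in ``c``)."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be nonnegative")
    if kp <= 0:
        raise ValueError(f"dermal permeability must be strictly positive, got {kp}")
    out = c * r.sa * kp * r.t_event * r.ev * r.ef * r.ed * 1e-3 / (r.bw * r.at)
    return float(out) if out.ndim == 0 and np.isscalar(r.ir) else out
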