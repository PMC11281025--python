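"""Distribution specifications for uncertain model inputs.

Every uncertain quantity in the risk model — intake rate, exposure
frequency, body weight, metal concentrations — is described by a small
declarative :class:`DistributionSpec`.  A spec can be collapsed to a
deterministic point value (for point-estimate risk assessment) or sampled
with a seeded :class:`numpy.random.Generator` (for Monte Carlo runs).

Supported families
------------------
``point``
    A degenerate distribution; ``params = {"value": v}``.
``normal``
    Gaussian; ``params = {"mean": m, "sd": s}``.
``triangular``
    ``params = {"min": a, "mode": c, "max": b}`` with ``a <= c <= b``.
``lognormal``
    Parameterised by the *natural-scale* mean and SD,
    ``params = {"mean": m, "sd": s}``; the log-scale parameters are
    recovered by moment inversion (see :func:`lognormal_log_params`).
``empirical``
    Resampling with replacement from ``params = {"values": [...]}``.

An optional ``lower_trunc`` (and ``upper_trunc``) bound truncates the
distribution by rejection resampling, so the sampled mass is exactly the
conditional distribution above (below) the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["DistributionSpec", "lognormal_log_params"]

_FAMILIES = ("point", "normal", "triangular", "lognormal", "empirical")


def lognormal_log_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale ``(mu, sigma)`` of a lognormal with the given natural moments.

    Moment inversion: ``sigma^2 = ln(1 + (sd/mean)^2)`` and
    ``mu = ln(mean) - sigma^2 / 2``, so that ``E[X] = mean`` and
    ``SD[X] = sd`` exactly.

    Raises
    ------
    ValueError
        If ``mean <= 0`` or ``sd < 0``.
    """
    if mean <= 0:
        raise ValueError(f"lognormal natural-scale mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"lognormal natural-scale sd must be >= 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of one uncertain scalar input."""

    family: str
    params: dict[str, Any] = field(default_factory=dict)
    lower_trunc: float | None = None
    upper_trunc: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; expected one of {_FAMILIES}"
            )
        p = self.params
        if self.family == "point":
            self._require(p, "value")
        elif self.family == "normal":
            self._require(p, "mean", "sd")
            if p["sd"] < 0:
                raise ValueError(f"normal sd must be >= 0, got {p['sd']}")
        elif self.family == "triangular":
            self._require(p, "min", "mode", "max")
            a, c, b = p["min"], p["mode"], p["max"]
            if not (a <= c <= b):
                raise ValueError(f"triangular requires min <= mode <= max, got {a}, {c}, {b}")
            if not a < b:
                raise ValueError(f"triangular requires min < max, got min={a}, max={b}")
        elif self.family == "lognormal":
            self._require(p, "mean", "sd")
            lognormal_log_params(p["mean"], p["sd"])  # validates
        elif self.family == "empirical":
            self._require(p, "values")
            if len(p["values"]) == 0:
                raise ValueError("empirical family requires at least one value")
        if (
            self.lower_trunc is not None
            and self.upper_trunc is not None
            and self.lower_trunc >= self.upper_trunc
        ):
            raise ValueError("lower_trunc must be below upper_trunc")

    @staticmethod
    def _require(params: dict[str, Any], *keys: str) -> None:
        missing = [k for k in keys if k not in params]
        if missing:
            raise ValueError(f"missing distribution parameter(s): {', '.join(missing)}")

    # -- deterministic views -------------------------------------------------

    def point_value(self) -> float:
        """Collapse to the point-estimate convention.

        Mean for ``normal`` and ``lognormal``, mode (most probable value)
        for ``triangular``, the value itself for ``point``, and the sample
        mean for ``empirical``.
        """
        p = self.params
        if self.family == "point":
            return float(p["value"])
        if self.family in ("normal", "lognormal"):
            return float(p["mean"])
        if self.family == "triangular":
            return float(p["mode"])
        return float(np.mean(p["values"]))

    def mean(self) -> float:
        """Analytic mean of the (untruncated) distribution."""
        p = self.params
        if self.family == "point":
            return float(p["value"])
        if self.family in ("normal", "lognormal"):
            return float(p["mean"])
        if self.family == "triangular":
            return (p["min"] + p["mode"] + p["max"]) / 3.0
        return float(np.mean(p["values"]))

    def sd(self) -> float:
        """Analytic standard deviation of the (untruncated) distribution."""
        p = self.params
        if self.family == "point":
            return 0.0
        if self.family in ("normal", "lognormal"):
            return float(p["sd"])
        if self.family == "triangular":
            a, c, b = p["min"], p["mode"], p["max"]
            return math.sqrt((a * a + b * b + c * c - a * b - a * c - b * c) / 18.0)
        return float(np.std(p["values"], ddof=1)) if len(p["values"]) > 1 else 0.0

    # -- sampling ------------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values, honouring the truncation bounds.

        Truncation is by rejection: out-of-bound draws are redrawn, so the
        result follows the conditional distribution inside the bounds.  A
        degenerate case (all mass outside the bounds) raises after a bounded
        number of attempts.
        """
        draw = self._draw(rng, size)
        lo, hi = self.lower_trunc, self.upper_trunc
        if lo is None and hi is None:
            return draw
        for _ in range(1000):
            bad = np.zeros(draw.shape, dtype=bool)
            if lo is not None:
                bad |= draw < lo
            if hi is not None:
                bad |= draw > hi
            n_bad = int(bad.sum())
            if n_bad == 0:
                return draw
            if self.family == "point" or (self.family == "normal" and self.params["sd"] == 0):
                raise ValueError("degenerate distribution lies outside its truncation bounds")
            draw[bad] = self._draw(rng, n_bad)
        raise RuntimeError("truncation rejection sampling failed to converge")

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(size, float(p["value"]))
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.family == "triangular":
            if p["min"] == p["mode"] == p["max"]:
                return np.full(size, float(p["mode"]))
            return rng.triangular(p["min"], p["mode"], p["max"], size)
        if self.family == "lognormal":
            if p["sd"] == 0:
                return np.full(size, float(p["mean"]))
            mu, sigma = lognormal_log_params(p["mean"], p["sd"])
            return rng.lognormal(mu, sigma, size)
        values = np.asarray(p["values"], dtype=float)
        return rng.choice(values, size=size, replace=True)

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"family": self.family, "params": dict(self.params)}
        if self.lower_trunc is not None:
            d["lower_trunc"] = self.lower_trunc
        if self.upper_trunc is not None:
            d["upper_trunc"] = self.upper_trunc
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DistributionSpec":
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            lower_trunc=d.get("lower_trunc"),
            upper_trunc=d.get("upper_trunc"),
        )
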