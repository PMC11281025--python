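"""Model constants: metals, exposure profiles, classification schemes.

The registry bundles every constant the assessment needs — regulatory
Class II thresholds of the Chinese surface-water quality standard
(GB 3838-2002), instrument detection limits, dermal permeabilities,
reference doses and cancer slope factors, population exposure parameters,
and the contamination / risk classification schemes.  Defaults are shipped
as a human-editable YAML file inside the package and every value can be
overridden from a user config file without touching code.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable

import yaml

from .distributions import DistributionSpec

__all__ = [
    "Metal",
    "ExposureProfile",
    "ClassificationScheme",
    "Registry",
    "default_registry",
    "classify",
    "METALS",
    "POPULATIONS",
]

#: Canonical metal ordering used throughout outputs.
METALS = ("Hg", "As", "Cu", "Zn", "Pb", "Cd")
POPULATIONS = ("children", "adults")


@dataclass(frozen=True)
class Metal:
    """Per-metal constants.

    ``rfd_*`` (reference doses, µg/kg/d) and ``sf_*`` (cancer slope
    factors, (µg/kg/d)⁻¹) may be absent (``None``): a metal is assessable
    for the non-carcinogenic endpoint iff both reference doses are present,
    and for the carcinogenic endpoint iff both slope factors are present.
    """

    symbol: str
    class2_threshold: float  # µg/L
    detection_limit: float  # µg/L
    kp: float  # dermal permeability, cm/h
    rfd_ing: float | None = None
    rfd_derm: float | None = None
    sf_ing: float | None = None
    sf_derm: float | None = None

    def __post_init__(self) -> None:
        for name in ("class2_threshold", "detection_limit", "kp",
                     "rfd_ing", "rfd_derm", "sf_ing", "sf_derm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(
                    f"Metal {self.symbol!r}: field {name!r} must be strictly "
                    f"positive, got {v}"
                )

    @property
    def noncarcinogenic_assessable(self) -> bool:
        return self.rfd_ing is not None and self.rfd_derm is not None

    @property
    def carcinogenic_assessable(self) -> bool:
        return self.sf_ing is not None and self.sf_derm is not None

    def to_dict(self) -> dict[str, Any]:
        return {
            "class2_threshold": self.class2_threshold,
            "detection_limit": self.detection_limit,
            "kp": self.kp,
            "rfd_ing": self.rfd_ing,
            "rfd_derm": self.rfd_derm,
            "sf_ing": self.sf_ing,
            "sf_derm": self.sf_derm,
        }


@dataclass(frozen=True)
class ExposureProfile:
    """One population's exposure parameters.

    ``ir`` (L/day), ``ef`` (days/year) and ``bw`` (kg) are distribution
    specs; the remaining parameters are fixed scalars: ``ed`` exposure
    duration (years), ``at_noncancer``/``at_cancer`` averaging times
    (days), ``sa`` skin surface area (cm²), ``t_event`` duration of one
    water-contact event (h/event), ``ev`` event frequency (events/day).
    """

    population: str
    ir: DistributionSpec
    ef: DistributionSpec
    ed: float
    bw: DistributionSpec
    at_noncancer: float
    at_cancer: float
    sa: float
    t_event: float
    ev: float

    def __post_init__(self) -> None:
        for name in ("ed", "at_noncancer", "at_cancer", "sa", "t_event", "ev"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(
                    f"ExposureProfile {self.population!r}: field {name!r} "
                    f"must be strictly positive, got {v}"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "ir": self.ir.to_dict(),
            "ef": self.ef.to_dict(),
            "ed": self.ed,
            "bw": self.bw.to_dict(),
            "at_noncancer": self.at_noncancer,
            "at_cancer": self.at_cancer,
            "sa": self.sa,
            "t_event": self.t_event,
            "ev": self.ev,
        }

    @classmethod
    def from_dict(cls, population: str, d: dict[str, Any]) -> "ExposureProfile":
        return cls(
            population=population,
            ir=DistributionSpec.from_dict(d["ir"]),
            ef=DistributionSpec.from_dict(d["ef"]),
            ed=d["ed"],
            bw=DistributionSpec.from_dict(d["bw"]),
            at_noncancer=d["at_noncancer"],
            at_cancer=d["at_cancer"],
            sa=d["sa"],
            t_event=d["t_event"],
            ev=d["ev"],
        )


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered severity bins over the nonnegative reals.

    ``bins`` is a least-to-most-severe list of ``(upper, label,
    inclusive)``: a value belongs to the first bin whose upper bound it is
    below (or equals, when the bound is inclusive).  The last bin must be
    unbounded (``upper = inf``) so every nonnegative value maps to exactly
    one label.
    """

    name: str
    bins: tuple[tuple[float, str, bool], ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError(f"scheme {self.name!r}: needs at least one bin")
        uppers = [b[0] for b in self.bins]
        if any(u2 <= u1 for u1, u2 in zip(uppers, uppers[1:])):
            raise ValueError(f"scheme {self.name!r}: bin upper bounds must increase")
        if not math.isinf(uppers[-1]):
            raise ValueError(f"scheme {self.name!r}: last bin must be unbounded above")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b[1] for b in self.bins)

    def classify(self, value: float) -> str:
        if value < 0 or math.isnan(value):
            raise ValueError(
                f"scheme {self.name!r}: cannot classify negative or NaN value {value}"
            )
        for upper, label, inclusive in self.bins:
            if value < upper or (inclusive and value == upper):
                return label
        return self.bins[-1][1]  # value == inf

    def severity(self, label: str) -> int:
        """Index of *label* in severity order (0 = least severe)."""
        return self.labels.index(label)

    def to_list(self) -> list[dict[str, Any]]:
        return [{"upper": u, "label": lab, "inclusive": inc} for u, lab, inc in self.bins]

    @classmethod
    def from_list(cls, name: str, bins: Iterable[dict[str, Any]]) -> "ClassificationScheme":
        return cls(
            name=name,
            bins=tuple((float(b["upper"]), str(b["label"]), bool(b["inclusive"])) for b in bins),
        )


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Map a nonnegative value to its severity label under *scheme*."""
    return scheme.classify(value)


@dataclass(frozen=True)
class Registry:
    """Validated bundle of all model constants."""

    metals: dict[str, Metal]
    profiles: dict[str, ExposureProfile]
    schemes: dict[str, ClassificationScheme]

    def metal(self, symbol: str) -> Metal:
        try:
            return self.metals[symbol]
        except KeyError:
            raise KeyError(f"no constants registered for metal {symbol!r}") from None

    def profile(self, population: str) -> ExposureProfile:
        try:
            return self.profiles[population]
        except KeyError:
            raise KeyError(f"no exposure profile for population {population!r}") from None

    def scheme(self, name: str) -> ClassificationScheme:
        try:
            return self.schemes[name]
        except KeyError:
            raise KeyError(f"no classification scheme named {name!r}") from None

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "metals": {sym: m.to_dict() for sym, m in self.metals.items()},
            "exposure_profiles": {pop: p.to_dict() for pop, p in self.profiles.items()},
            "classification_schemes": {n: s.to_list() for n, s in self.schemes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Registry":
        metals = {sym: Metal(symbol=sym, **md) for sym, md in d["metals"].items()}
        profiles = {
            pop: ExposureProfile.from_dict(pop, pd)
            for pop, pd in d["exposure_profiles"].items()
        }
        schemes = {
            n: ClassificationScheme.from_list(n, bins)
            for n, bins in d["classification_schemes"].items()
        }
        return cls(metals=metals, profiles=profiles, schemes=schemes)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "Registry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _default_dict() -> dict[str, Any]:
    text = resources.files("wetlandrisk").joinpath("data/default_config.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def default_registry(config_path: str | None = None) -> Registry:
    """Build the registry from the shipped defaults.

    Parameters
    ----------
    config_path
        Optional YAML file whose entries override individual defaults
        (deep merge; anything not mentioned keeps its default).  Overrides
        failing a type invariant raise :class:`ValueError` naming the
        offending field.
    """
    d = _default_dict()
    if config_path is not None:
        with open(config_path, encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
        d = _deep_merge(d, override)
    return Registry.from_dict(d)
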