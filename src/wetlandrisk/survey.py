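"""Published summary statistics of the Urumqi small-wetland survey.

The raw per-sample chemistry of the 36 overlying-water samples (20 urban,
16 rural small wetlands, sampled October 2023) was not deposited; what is
public is the per-group summary table — max, min, mean and SD of each
metal's concentration — plus the group-average single-factor pollution
indices.  Those summaries are recorded here verbatim: they are the targets
the synthetic generator emulates and the inputs to the group-level
contamination and point-risk computations.

All concentrations in µg/L.
"""

from __future__ import annotations

from .synthetic import GroupProfile, MetalStats

__all__ = [
    "urban_profile",
    "rural_profile",
    "group_profile",
    "GROUP_MEAN_CONCENTRATIONS",
    "REPORTED_MEAN_POLLUTION_INDEX",
    "PH_RANGE",
    "EC_RANGE",
]

#: pH and electrical-conductivity ranges observed across the 36 samples.
PH_RANGE = (6.84, 8.36)
EC_RANGE = (423.0, 5820.0)  # µS/cm

_URBAN = {
    #        max     min     mean    sd
    "Hg": (0.88, 0.04, 0.16, 0.21),
    "As": (8.30, 0.50, 2.70, 1.80),
    "Cu": (73.0, 1.48, 37.76, 20.46),
    "Zn": (298.0, 7.44, 93.18, 54.33),
    "Pb": (3.53, 0.10, 1.20, 0.86),
    "Cd": (0.34, 0.05, 0.09, 0.06),
}

_RURAL = {
    "Hg": (1.13, 0.04, 0.25, 0.31),
    "As": (7.60, 2.10, 4.15, 1.79),
    "Cu": (232.0, 1.22, 63.29, 49.42),
    "Zn": (344.0, 78.60, 175.65, 71.00),
    "Pb": (3.70, 0.97, 2.18, 0.89),
    "Cd": (0.27, 0.05, 0.14, 0.06),
}

#: Group-mean concentrations (µg/L), the inputs to group-level indices
#: and point-estimate risk.
GROUP_MEAN_CONCENTRATIONS = {
    "urban": {m: v[2] for m, v in _URBAN.items()},
    "rural": {m: v[2] for m, v in _RURAL.items()},
}

#: Group-average single-factor pollution indices as published (two
#: decimals).  Note the published urban Hg value 3.21 carries one more
#: digit than mean/threshold = 0.16/0.05 = 3.2 recomputed from the rounded
#: mean; the published figures are kept as the reference.
REPORTED_MEAN_POLLUTION_INDEX = {
    "urban": {"Hg": 3.21, "As": 0.05, "Cu": 0.04, "Zn": 0.09, "Pb": 0.12, "Cd": 0.02},
    "rural": {"Hg": 4.98, "As": 0.08, "Cu": 0.06, "Zn": 0.18, "Pb": 0.22, "Cd": 0.03},
}


def _profile(group: str, n: int, table: dict) -> GroupProfile:
    return GroupProfile(
        group=group,
        n_samples=n,
        metals={
            m: MetalStats(target_max=mx, target_min=mn, target_mean=mean, target_sd=sd)
            for m, (mx, mn, mean, sd) in table.items()
        },
    )


def urban_profile() -> GroupProfile:
    """Summary-statistic targets for the 20 urban small-wetland samples."""
    return _profile("urban", 20, _URBAN)


def rural_profile() -> GroupProfile:
    """Summary-statistic targets for the 16 rural small-wetland samples."""
    return _profile("rural", 16, _RURAL)


def group_profile(group: str) -> GroupProfile:
    if group == "urban":
        return urban_profile()
    if group == "rural":
        return rural_profile()
    raise ValueError(f"unknown group {group!r}; expected 'urban' or 'rural'")
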