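"""Radiation use, conversion and partitioning efficiencies.

Definitions (all percentages):

    RUE (g MJ^-1)  = TB / PARint            biomass per intercepted PAR
    epsilon_c (%)  = 100 * RUE / 57.14      conversion efficiency
    epsilon_p (%)  = 100 * HI               partitioning efficiency

57.14 g MJ^-1 is the biomass equivalent of an energy content of
17.5 MJ kg^-1.  Relative efficiencies divide an observed percentage by the
theoretical maximum for the crop's photosynthetic and harvest-organ type
(epsilon_i max 90% for all crops; epsilon_c max 9.4% C3 / 12.3% C4;
epsilon_p max 65% for grain and seed crops, 90% for tuber, root and
stem-harvested crops), enabling a cross-crop ranking from literature maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "EfficiencyConstants",
    "EfficiencySet",
    "rue",
    "epsilon_c",
    "epsilon_p",
    "relative_efficiency",
    "round_half_up",
    "CROSS_CROP_LITERATURE",
    "crop_comparison_table",
]


@dataclass(frozen=True)
class EfficiencyConstants:
    """Energy-content constants and theoretical efficiency maxima."""

    biomass_energy: float = 17.5      # MJ per kg dry biomass
    biomass_conversion: float = 57.14  # g biomass per MJ (= 1000/17.5, rounded)
    seed_energy: float = 23.0          # MJ per kg seed mass
    max_ei: float = 90.0               # % — all crops
    max_ec_c3: float = 9.4             # % — C3 photosynthesis
    max_ec_c4: float = 12.3            # % — C4 photosynthesis
    max_ep_grain: float = 65.0         # % — grain and seed crops
    max_ep_tuber: float = 90.0         # % — tuber, root and stem crops

    def __post_init__(self) -> None:
        if abs(self.biomass_conversion - 1000.0 / self.biomass_energy) > 0.01:
            raise ValueError(
                "biomass_conversion inconsistent with 1000/biomass_energy"
            )


DEFAULT_CONSTANTS = EfficiencyConstants()


@dataclass(frozen=True)
class EfficiencySet:
    """Per-accession efficiency record (percent scales, rue in g MJ^-1)."""

    accession_id: str
    epsilon_i: float
    epsilon_c: float
    epsilon_p: float
    rue: float
    par_int: float
    ty: float

    def __post_init__(self) -> None:
        for name in ("epsilon_i", "epsilon_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.epsilon_c < 0:
            raise ValueError("epsilon_c must be >= 0")


def rue(tb: float, par_int: float, plant_area: float) -> float:
    """Radiation use efficiency: (TB per m^2) / PARint, g MJ^-1.

    ``tb`` is g per plant; ``par_int`` MJ m^-2; ``plant_area`` m^2.
    """
    if par_int <= 0:
        raise ValueError("PARint must be > 0 to define RUE")
    if plant_area <= 0:
        raise ValueError("plant_area must be > 0")
    return (tb / plant_area) / par_int


def epsilon_c(rue_value: float, constants: EfficiencyConstants = DEFAULT_CONSTANTS) -> float:
    """Conversion efficiency (%) from RUE."""
    if rue_value < 0:
        raise ValueError("rue must be >= 0")
    return 100.0 * rue_value / constants.biomass_conversion


def epsilon_p(hi: float) -> float:
    """Partitioning efficiency (%) from the harvest-index fraction."""
    if not 0.0 <= hi <= 1.0:
        raise ValueError(f"harvest index {hi} outside [0, 1]")
    return 100.0 * hi


def relative_efficiency(value: float, theoretical_max: float) -> float:
    """Ratio of an observed efficiency to its theoretical maximum."""
    if theoretical_max <= 0:
        raise ValueError("theoretical maximum must be > 0")
    return value / theoretical_max


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used when reporting relative efficiencies."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


#: Literature maxima of the three efficiencies for major crops
#: (percent scales).  ``crop_type`` drives which theoretical epsilon_p
#: maximum applies: seed crops (grain, leguminous) 65%, all others 90%.
CROSS_CROP_LITERATURE = pd.DataFrame(
    [
        ("Sugarcane", "C4", "perennial grass", 95.0, 8.0, 81.2),
        ("Maize", "C4", "grain", 55.0, 8.7, 47.1),
        ("Sorghum", "C4", "grain", 50.1, 8.0, 20.0),
        ("Winter wheat", "C3", "grain", 97.8, 7.5, 44.0),
        ("Rice", "C3", "grain", 80.0, 6.6, 62.0),
        ("Soybean", "C3", "leguminous", 89.0, 4.3, 60.0),
        ("Sugar beet", "C3", "tuber root", 90.0, 6.2, 86.0),
        ("Cassava", "C3", "tuber root", 64.0, 1.4, 70.5),
        ("Sweetpotato", "C3", "tuber root", 91.0, 3.4, 46.0),
    ],
    columns=["crop", "plant_type", "crop_type", "epsilon_i", "epsilon_c", "epsilon_p"],
)

_SEED_CROP_TYPES = {"grain", "leguminous"}


def _max_ec(plant_type: str, constants: EfficiencyConstants) -> float:
    if plant_type == "C3":
        return constants.max_ec_c3
    if plant_type == "C4":
        return constants.max_ec_c4
    raise ValueError(f"unknown plant type {plant_type!r}")


def _max_ep(crop_type: str, constants: EfficiencyConstants) -> float:
    known = _SEED_CROP_TYPES | {"tuber", "tuber root", "perennial grass"}
    if crop_type not in known:
        raise ValueError(f"unknown crop type {crop_type!r}")
    return constants.max_ep_grain if crop_type in _SEED_CROP_TYPES else constants.max_ep_tuber


def crop_comparison_table(
    potato_max: tuple[float, float, float],
    entries: pd.DataFrame | None = None,
    constants: EfficiencyConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Cross-crop table of relative efficiencies with per-column ranks.

    ``potato_max`` is the trial's highest (epsilon_i, epsilon_c, epsilon_p);
    the potato row (C3 tuber crop) is injected into the literature table and
    every crop's efficiencies are divided by its type-appropriate theoretical
    maximum.  Rank 1 = highest relative efficiency.
    """
    base = CROSS_CROP_LITERATURE if entries is None else entries
    table = base.copy()
    table.loc[len(table)] = ["Potato", "C3", "tuber", *potato_max]
    table["rel_epsilon_i"] = [
        relative_efficiency(v, constants.max_ei) for v in table["epsilon_i"]
    ]
    table["rel_epsilon_c"] = [
        relative_efficiency(v, _max_ec(pt, constants))
        for v, pt in zip(table["epsilon_c"], table["plant_type"])
    ]
    table["rel_epsilon_p"] = [
        relative_efficiency(v, _max_ep(ct, constants))
        for v, ct in zip(table["epsilon_p"], table["crop_type"])
    ]
    for col in ("rel_epsilon_i", "rel_epsilon_c", "rel_epsilon_p"):
        table[col.replace("rel_", "rank_")] = (
            table[col].rank(ascending=False, method="min").astype(int)
        )
    return table.set_index("crop")


def efficiency_set(
    accession_id: str,
    radiation,
    growth,
    plant_area: float,
    constants: EfficiencyConstants = DEFAULT_CONSTANTS,
) -> EfficiencySet:
    """Assemble the per-accession record from fitted radiation and growth."""
    r = rue(growth.tb, radiation.par_int_cum, plant_area)
    return EfficiencySet(
        accession_id=accession_id,
        epsilon_i=radiation.epsilon_i,
        epsilon_c=epsilon_c(r, constants),
        epsilon_p=epsilon_p(growth.hi),
        rue=r,
        par_int=radiation.par_int_cum,
        ty=growth.ty_sim,
    )
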