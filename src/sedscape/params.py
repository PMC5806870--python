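"""Land-use codes, parameter tables, and per-class model parameters.

Erodibility ranges and cover-factor bounds are packaged constants; the
per-run cover/retention values are resolved from a calibration member via
:func:`resolve_landuse_params`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LANDUSE_CODES",
    "PASTURE",
    "FOREST",
    "EUCALYPTUS",
    "ROAD",
    "MICRODAM",
    "GROWING_FOREST",
    "WATER",
    "CONVERTIBLE_CLASSES",
    "ERODIBILITY_TABLE",
    "C_RANGES",
    "PASTURE_SRE_RANGE",
    "FOREST_SRE_OPTIONS",
    "LandUseParams",
    "ErodibilityTable",
    "resolve_landuse_params",
    "erodibility_lookup",
]

# Integer class codes used in land-use rasters.
PASTURE = 1
FOREST = 2
EUCALYPTUS = 3
ROAD = 4
MICRODAM = 5
GROWING_FOREST = 6
WATER = 7

LANDUSE_CODES: dict[int, str] = {
    PASTURE: "pasture",
    FOREST: "forest",
    EUCALYPTUS: "eucalyptus",
    ROAD: "road",
    MICRODAM: "microdam",
    GROWING_FOREST: "growing_forest",
    WATER: "water",
}

# Classes eligible for conversion to forest in restoration scenarios.
# Roads, water bodies and micro-dams are never converted.
CONVERTIBLE_CLASSES: tuple[int, ...] = (PASTURE, EUCALYPTUS)

# Soil erodibility K (Mg h ha MJ^-1 mm^-1 ha^-1): {class: (min, mean, max)}.
ERODIBILITY_TABLE: dict[str, tuple[float, float, float]] = {
    "red_yellow_ultisol": (0.0139, 0.0252, 0.0386),
    "ochrept": (0.0093, 0.0245, 0.0398),
    "inceptisol": (0.0105, 0.0225, 0.0380),
    "udorthent": (0.0137, 0.0233, 0.0326),
    "fluvent": (0.0080, 0.0236, 0.0377),
}

# Soil class integer codes, in table order.
SOIL_CODES: dict[int, str] = {
    1: "red_yellow_ultisol",
    2: "ochrept",
    3: "inceptisol",
    4: "udorthent",
    5: "fluvent",
}

# Cover-factor calibration bounds per major land use: {class: (min, max)}.
C_RANGES: dict[str, tuple[float, float]] = {
    "pasture": (0.05, 0.22),
    "forest": (0.02, 0.09),
    "eucalyptus": (0.12, 0.30),
}

# Pasture sediment retention efficiency is calibrated within this range.
PASTURE_SRE_RANGE: tuple[float, float] = (0.05, 0.40)

# Forest sediment retention efficiency options used by the ensemble.
FOREST_SRE_OPTIONS: tuple[float, float] = (0.45, 0.65)


@dataclass
class ErodibilityTable:
    """Per-soil-class K ranges with min/mean/max options."""

    table: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(ERODIBILITY_TABLE)
    )

    def __post_init__(self) -> None:
        for cls, (kmin, kmean, kmax) in self.table.items():
            if not (kmin <= kmean <= kmax):
                raise ValueError(f"erodibility for {cls!r} not ordered: "
                                 f"{kmin} <= {kmean} <= {kmax} fails")

    def option(self, which: str) -> dict[str, float]:
        """Pick one K per class: ``which`` in {'min', 'mean', 'max'}."""
        idx = {"min": 0, "mean": 1, "max": 2}[which]
        return {cls: vals[idx] for cls, vals in self.table.items()}


def erodibility_lookup(which: str = "mean") -> dict[int, float]:
    """K by integer soil code for one option column."""
    opt = ErodibilityTable().option(which)
    return {code: opt[name] for code, name in SOIL_CODES.items()}


@dataclass
class LandUseParams:
    """Resolved per-class USLE and routing parameters.

    ``c_factor``, ``p_factor`` and ``sre`` map integer land-use codes to
    cover factor, support-practice factor, and sediment retention
    efficiency (fraction of through-passing sediment trapped per cell).
    """

    c_factor: dict[int, float]
    p_factor: dict[int, float]
    sre: dict[int, float]

    def __post_init__(self) -> None:
        for name, table in (("C", self.c_factor), ("P", self.p_factor),
                            ("SRE", self.sre)):
            for code, val in table.items():
                if not 0.0 <= val <= 1.0:
                    raise ValueError(
                        f"{name} for class {code} out of [0, 1]: {val}"
                    )


def resolve_landuse_params(
    pasture_c: float,
    forest_c: float,
    eucalyptus_c: float,
    pasture_sre: float,
    forest_sre: float,
) -> LandUseParams:
    """Expand calibrated/major-class values into the full class table.

    Fixed conventions: roads C=1, water C=0, micro-dams C=0 and SRE=1;
    growing forest takes the mean of pasture and forest for both C and SRE;
    eucalyptus SRE is the mean of pasture and forest SRE; P=1 everywhere
    (no support practices are modelled).
    """
    euc_sre = (pasture_sre + forest_sre) / 2.0
    c = {
        PASTURE: pasture_c,
        FOREST: forest_c,
        EUCALYPTUS: eucalyptus_c,
        ROAD: 1.0,
        MICRODAM: 0.0,
        GROWING_FOREST: (pasture_c + forest_c) / 2.0,
        WATER: 0.0,
    }
    sre = {
        PASTURE: pasture_sre,
        FOREST: forest_sre,
        EUCALYPTUS: euc_sre,
        ROAD: 0.0,
        MICRODAM: 1.0,
        GROWING_FOREST: (pasture_sre + forest_sre) / 2.0,
        WATER: 0.0,
    }
    p = {code: 1.0 for code in c}
    return LandUseParams(c_factor=c, p_factor=p, sre=sre)
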