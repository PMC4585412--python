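"""Per-plant aggregation of leaf records into 29 named traits.

The trait table groups into 6 size traits, 7 colour traits and 16 shape
traits:

* size — LN (leaf number), TLA (total leaf area), GLA (green leaf area),
  ALA/MLA (average/maximum leaf area), LASD (leaf-area SD);
* colour — GLA2/3/4 (area in each green class), GLAR2/3/4 (their ratios
  over GLA), GLCC (area-weighted mean green-class index,
  (2·GLA2 + 3·GLA3 + 4·GLA4)/GLA — a monotone greenness score);
* shape — average/maximum/SD of leaf length, width, perimeter and
  compactness (12 traits), plus ALWR/MLWR (average and maximum
  length-to-width ratio, each formed from the corresponding aggregated
  lengths and widths), APAR = ALP/ALA and MPAR = the per-leaf maximum of
  perimeter/area.

Averages are arithmetic means over the leaves of one plant, maxima are
per-leaf maxima, and SDs are population SDs (divide by n).  For a plant
whose leaves are identical W×L rectangles, ALWN = ALL·ALW·LN equals TLA
exactly, and APAR reduces to 2/ALW + 2/ALL (→ 2/ALW for long blades),
which is the rectangular-blade approximation used to sanity-check the
shape traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .morphometrics import LeafRecord

__all__ = [
    "PlantTraits",
    "SIZE_TRAITS",
    "COLOUR_TRAITS",
    "SHAPE_TRAITS",
    "TRAIT_NAMES",
    "aggregate",
    "alwn",
    "mlwn",
    "apar_rectangular_approx",
]

SIZE_TRAITS = ("LN", "TLA", "GLA", "ALA", "MLA", "LASD")
COLOUR_TRAITS = ("GLA2", "GLA3", "GLA4", "GLAR2", "GLAR3", "GLAR4", "GLCC")
SHAPE_TRAITS = (
    "ALL", "MLL", "LLSD",
    "ALW", "MLW", "LWSD",
    "ALP", "MLP", "LPSD",
    "ALC", "MLC", "LCSD",
    "ALWR", "MLWR", "APAR", "MPAR",
)
#: The 29 trait names, in reporting order (6 size / 7 colour / 16 shape).
TRAIT_NAMES = SIZE_TRAITS + COLOUR_TRAITS + SHAPE_TRAITS


@dataclass(frozen=True)
class PlantTraits:
    """The 29 per-plant trait values.

    Areas in mm², lengths in mm, APAR/MPAR in mm⁻¹; ratios and
    compactness dimensionless.  Colour ratios and GLCC are NaN when the
    plant has no green leaf area.
    """

    LN: int
    TLA: float
    GLA: float
    ALA: float
    MLA: float
    LASD: float
    GLA2: float
    GLA3: float
    GLA4: float
    GLAR2: float
    GLAR3: float
    GLAR4: float
    GLCC: float
    ALL: float
    MLL: float
    LLSD: float
    ALW: float
    MLW: float
    LWSD: float
    ALP: float
    MLP: float
    LPSD: float
    ALC: float
    MLC: float
    LCSD: float
    ALWR: float
    MLWR: float
    APAR: float
    MPAR: float

    def to_dict(self) -> dict[str, float]:
        """Ordered mapping of the 29 trait values."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __getitem__(self, name: str) -> float:
        if name not in TRAIT_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _pop_sd(values: np.ndarray) -> float:
    return float(np.std(values))  # population SD (ddof=0)


def aggregate(records: list[LeafRecord]) -> PlantTraits:
    """Aggregate the leaves of one plant into the 29-trait vector."""
    if not records:
        raise ValueError("cannot aggregate an empty list of leaf records")

    areas = np.array([r.area_mm2 for r in records], dtype=float)
    lengths = np.array([r.length_mm for r in records], dtype=float)
    widths = np.array([r.width_mm for r in records], dtype=float)
    perims = np.array([r.perimeter_mm for r in records], dtype=float)
    compact = np.array([r.compactness for r in records], dtype=float)
    g2 = sum(r.class_areas_mm2.get("green-2", 0.0) for r in records)
    g3 = sum(r.class_areas_mm2.get("green-3", 0.0) for r in records)
    g4 = sum(r.class_areas_mm2.get("green-4", 0.0) for r in records)

    gla = g2 + g3 + g4
    if gla > 0:
        glar2, glar3, glar4 = g2 / gla, g3 / gla, g4 / gla
        glcc = (2.0 * g2 + 3.0 * g3 + 4.0 * g4) / gla
    else:
        glar2 = glar3 = glar4 = glcc = math.nan

    alw = float(widths.mean())
    all_ = float(lengths.mean())
    alp = float(perims.mean())
    ala = float(areas.mean())

    return PlantTraits(
        LN=len(records),
        TLA=float(areas.sum()),
        GLA=gla,
        ALA=ala,
        MLA=float(areas.max()),
        LASD=_pop_sd(areas),
        GLA2=g2,
        GLA3=g3,
        GLA4=g4,
        GLAR2=glar2,
        GLAR3=glar3,
        GLAR4=glar4,
        GLCC=glcc,
        ALL=all_,
        MLL=float(lengths.max()),
        LLSD=_pop_sd(lengths),
        ALW=alw,
        MLW=float(widths.max()),
        LWSD=_pop_sd(widths),
        ALP=alp,
        MLP=float(perims.max()),
        LPSD=_pop_sd(perims),
        ALC=float(compact.mean()),
        MLC=float(compact.max()),
        LCSD=_pop_sd(compact),
        ALWR=all_ / alw,
        MLWR=float(lengths.max()) / float(widths.max()),
        APAR=alp / ala,
        MPAR=float((perims / areas).max()),
    )


def alwn(traits: PlantTraits) -> float:
    """Average leaf length × average leaf width × leaf number (mm² × count).

    For a plant of identical rectangular blades this equals TLA exactly;
    on real plants it is a strong linear predictor of GLA.
    """
    return traits.ALL * traits.ALW * traits.LN


def mlwn(traits: PlantTraits) -> float:
    """Maximum leaf length × maximum leaf width × leaf number."""
    return traits.MLL * traits.MLW * traits.LN


def apar_rectangular_approx(all_mm: float, alw_mm: float) -> tuple[float, float]:
    """Rectangular-blade approximations of APAR (mm⁻¹).

    Returns ``(2/ALW + 2/ALL, 2/ALW)`` — the exact perimeter/area ratio of
    an ALL × ALW rectangle, and its long-blade limit where ALL ≫ ALW.
    """
    if all_mm <= 0 or alw_mm <= 0:
        raise ValueError("leaf dimensions must be strictly positive")
    return 2.0 / alw_mm + 2.0 / all_mm, 2.0 / alw_mm
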