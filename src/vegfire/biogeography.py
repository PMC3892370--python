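"""Annual lifeform mixes and vegetation classification from carbon pools.

The tree stratum is a mix of evergreen needleleaf and deciduous broadleaf
types set by smoothed climate (or forced pure evergreen under the
evergreen constraint); the grass stratum splits C3/C4 by growing-season
temperature.  The vegetation class of a cell is a pure step function of its
live aboveground tree carbon.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from .params import BiogeographyParams

__all__ = ["VegClass", "lifeform_mix", "classify_vegetation", "vegetation_fractions"]


class VegClass(IntEnum):
    """Vegetation classes ordered by woody biomass."""

    GRASSLAND = 0
    SHRUBLAND = 1
    WOODLAND = 2
    FOREST = 3


def lifeform_mix(min_temp_coldest: np.ndarray, gs_precip: np.ndarray,
                 params: BiogeographyParams | None = None,
                 evergreen_constraint: bool = False,
                 gs_temp: np.ndarray | None = None) -> dict:
    """Tree-type and grass-type fractions from smoothed climate.

    The deciduous-broadleaf fraction interpolates bilinearly between the
    pure-evergreen corner (cold winters, dry growing season) and the pure
    deciduous corner, with the two mixed corners at 0.5; climates at or
    beyond a pure corner give a pure type.  With ``evergreen_constraint``
    the tree stratum is forced to 100% evergreen needleleaf regardless of
    climate (the constraint is idempotent).

    Returns a dict with ``evergreen`` / ``deciduous`` tree fractions and
    ``c3`` / ``c4`` grass fractions (each stratum sums to 1).
    """
    params = params or BiogeographyParams()
    mt = np.asarray(min_temp_coldest, float)
    gsp = np.asarray(gs_precip, float)
    mt_ev, gsp_ev = params.evergreen_corner
    mt_de, gsp_de = params.deciduous_corner

    u = np.clip((mt - mt_ev) / (mt_de - mt_ev), 0.0, 1.0)
    v = np.clip((gsp - gsp_ev) / (gsp_de - gsp_ev), 0.0, 1.0)
    deciduous = np.zeros_like(u) if evergreen_constraint else 0.5 * (u + v)

    if gs_temp is None:
        gs_temp = np.zeros_like(mt)
    c4 = np.clip((np.asarray(gs_temp, float) - params.c4_t_lo)
                 / (params.c4_t_hi - params.c4_t_lo), 0.0, 1.0)
    return {"evergreen": 1.0 - deciduous, "deciduous": deciduous,
            "c3": 1.0 - c4, "c4": c4}


def classify_vegetation(live_tree_c, params: BiogeographyParams | None = None):
    """Vegetation class from live aboveground tree carbon (g C m^-2).

    Forest at and above 3000, woodland on [1150, 3000), shrubland on
    [80, 1150), grassland below 80 (default thresholds; the forest boundary
    belongs to forest, the lower boundaries to the named class).
    """
    params = params or BiogeographyParams()
    c = np.asarray(live_tree_c, float)
    if np.any(c < 0):
        raise ValueError("live tree carbon must be non-negative")
    cls = np.select(
        [c >= params.forest_min, c >= params.woodland_min, c >= params.shrubland_min],
        [VegClass.FOREST, VegClass.WOODLAND, VegClass.SHRUBLAND],
        default=VegClass.GRASSLAND,
    )
    if np.isscalar(live_tree_c) or np.ndim(live_tree_c) == 0:
        return VegClass(int(cls))
    return cls.astype(np.int8)


def vegetation_fractions(classes) -> dict:
    """Percentage of cells per vegetation class (sums to 100)."""
    arr = np.asarray(classes)
    if arr.size == 0:
        raise ValueError("empty grid")
    out = {}
    for vc in VegClass:
        out[vc.name.lower()] = 100.0 * float(np.count_nonzero(arr == vc)) / arr.size
    return out
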