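"""Individual-tree and plot-level stem volume from two-way volume equations.

The two-way ("binary") volume equation predicts stem volume from diameter at
breast height D (cm) and total height H (m):

    V = a * D**b * H**c        [m^3]

with species-specific coefficients for the three conifers of the study
system (Northeast-China plantation species).  Plot volume per hectare is the
sum of tree volumes divided by the plot area expressed in hectares, so the
response M carries units of m^3/ha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["VolumeParams", "VOLUME_TABLE", "tree_volume", "plot_volume_per_ha"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeParams:
    species: str
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ValueError("volume coefficients must be positive")


#: Two-way volume-table coefficients (V = a D^b H^c; D in cm, H in m, V in m^3).
VOLUME_TABLE: Mapping[str, VolumeParams] = {
    "larix": VolumeParams("larix", 0.00005017, 1.7583, 1.14967),        # Larix olgensis
    "koraiensis": VolumeParams("koraiensis", 0.00006353, 1.9436, 0.89689),  # Pinus koraiensis
    "sylvestris": VolumeParams("sylvestris", 0.00006938, 1.7631, 1.03701),  # Pinus sylvestris var. mongolica
}


def tree_volume(species: str, dbh_cm, height_m):
    """Stem volume (m^3) of one tree or an array of trees of one species."""
    try:
        p = VOLUME_TABLE[species]
    except KeyError:
        raise KeyError(f"no volume parameters registered for species {species!r}") from None
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(dbh_cm <= 0) or np.any(height_m <= 0):
        raise ValueError("dbh_cm and height_m must be positive")
    v = p.a * dbh_cm ** p.b * height_m ** p.c
    return float(v) if v.ndim == 0 else v


def plot_volume_per_ha(trees: pd.DataFrame | Iterable, area_ha: float) -> float:
    """Plot volume M (m^3/ha): sum of tree volumes over the plot area in ha.

    ``trees`` is a DataFrame with columns ``species``, ``dbh_cm``, ``height_m``
    (extra columns ignored).  An empty tree list is a valid treeless plot and
    yields 0.
    """
    if area_ha <= 0:
        raise ValueError("area_ha must be positive")
    if not isinstance(trees, pd.DataFrame):
        trees = pd.DataFrame(list(trees))
    if len(trees) == 0:
        logger.info("plot with empty tree list: volume 0 m3/ha")
        return 0.0
    total = 0.0
    for species, grp in trees.groupby("species", observed=True):
        total += float(np.sum(tree_volume(str(species), grp["dbh_cm"].to_numpy(),
                                          grp["height_m"].to_numpy())))
    return total / float(area_ha)
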