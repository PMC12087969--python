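"""Habitable / habitable-but-inaccessible / uninhabitable maps through time.

Per-bin niche thresholds (min/max of each niche variable over the lineage's
tips and reconstructed branches in that bin) are projected onto the bin's
climate slice: a cell is habitable for a variable iff its value lies within
the [min, max] threshold; multi-variable mode intersects the per-variable
masks, single-variable mode (habitat mean annual temperature, H-MAT) uses one
variable alone.  Habitable cells are then partitioned by accessibility:
cells in realms reachable from the occupied realms through adjacency edges
whose dispersal multiplier exceeds 1e-6 are accessible (habitable); the
remaining habitable cells are habitable but inaccessible; all other cells are
uninhabitable.  Reachability is graph reachability on the epoch's
dispersal-multiplier graph — a documented concretization, recorded in the map
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .biogeo import RealmHistory
from .rasters import ClimateSlice

__all__ = ["HabitabilityMap", "project_thresholds", "partition_accessibility"]

CLASSES = ("habitable", "inaccessible", "uninhabitable")


@dataclass
class HabitabilityMap:
    classes: np.ndarray          # strings per cell, one of CLASSES
    age_ma: float
    meta: dict = field(default_factory=dict)

    def area_fractions(self) -> dict:
        tot = self.classes.size
        return {c: float((self.classes == c).sum()) / tot for c in CLASSES}


def project_thresholds(thresholds: dict, slc: ClimateSlice,
                       variables=None) -> np.ndarray:
    """Boolean habitable mask for one slice from per-variable [min, max] bounds.

    ``thresholds`` maps variable name -> (vmin, vmax) for the slice's bin.
    ``variables`` restricts (and orders) the variables used; a single-element
    list gives the single-variable (e.g. H-MAT) mode.  Narrowing any
    threshold can only remove habitable cells.
    """
    names = list(thresholds) if variables is None else list(variables)
    missing = [v for v in names if v not in slc.variables]
    if missing:
        raise ValueError(f"slice is missing variables: {missing}")
    mask = np.ones(slc.shape, dtype=bool)
    for v in names:
        vmin, vmax = thresholds[v]
        g = slc.variables[v]
        mask &= (g >= vmin) & (g <= vmax)
    return mask


def partition_accessibility(habitable_mask: np.ndarray, occupied_realms,
                            history: RealmHistory, age_ma: float,
                            realm_of_cell: np.ndarray,
                            barrier_cutoff: float = 1e-6) -> HabitabilityMap:
    """Split the habitable mask into accessible and inaccessible classes.

    ``realm_of_cell`` assigns every cell a realm index; realms reachable from
    any occupied realm through edges with multiplier > ``barrier_cutoff`` in
    the epoch containing ``age_ma`` are accessible.  With no occupied realm,
    every habitable cell is inaccessible (warned via metadata flag).
    """
    if habitable_mask.shape != realm_of_cell.shape:
        raise ValueError("mask and realm grid shapes differ")
    occupied = sorted(set(int(r) for r in occupied_realms))
    n = history.n_realms
    mult = history.epoch_at(age_ma).multipliers
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            if mult[a, b] > barrier_cutoff:
                g.add_edge(a, b)
    reachable: set[int] = set()
    for r in occupied:
        reachable |= nx.node_connected_component(g, r)
    classes = np.full(habitable_mask.shape, "uninhabitable", dtype=object)
    acc = np.isin(realm_of_cell, sorted(reachable))
    classes[habitable_mask & acc] = "habitable"
    classes[habitable_mask & ~acc] = "inaccessible"
    return HabitabilityMap(
        classes=classes.astype(str), age_ma=age_ma,
        meta={"occupied_realms": occupied,
              "reachable_realms": sorted(reachable),
              "no_occupied_realm": len(occupied) == 0,
              "accessibility_rule":
                  f"graph reachability over multipliers > {barrier_cutoff}"})
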