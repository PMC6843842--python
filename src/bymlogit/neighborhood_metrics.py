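"""Objective built-environment (walkability) metrics on a gridded landscape.

Each area's urbanized land is a set of 100 m x 100 m grid cells.  Metrics:

* mean Euclidean distance from urbanized cell centres to the nearest
  destination of a class (public physical-activity facility, park, transit
  stop) — destinations anywhere may be nearest, not only those inside the
  area;
* population and intersection densities per km^2 of urbanized land;
* land-use mix (LUM), the 3-category entropy index over domestic /
  commercial / business floor areas, 0 (single use) to 1 (perfectly mixed).

All metrics are finally cut into tertiles (T1 lowest .. T3 highest) because
their effects on obesity are treated as nonlinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CELL_SIZE_M = 100.0
DESTINATION_CLASSES = ("pa_facility", "park", "transit")
FLOOR_CLASSES = ("domestic", "commercial", "business")

__all__ = [
    "Landscape",
    "AreaLandscape",
    "mean_grid_distance",
    "density",
    "land_use_mix",
    "tertile_categorize",
    "compute_metric_table",
    "CELL_SIZE_M",
    "DESTINATION_CLASSES",
    "FLOOR_CLASSES",
]


@dataclass
class AreaLandscape:
    """One area's synthetic geometry and attributes.

    ``cells`` holds integer (ix, iy) indices of 100 m urbanized grid cells;
    destination / intersection coordinates are in metres in the same frame.
    """

    area_id: str
    cells: np.ndarray  # (n_cells, 2) int
    destinations: Mapping[str, np.ndarray] = field(default_factory=dict)
    intersections: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    population: int = 0
    floor_areas: Mapping[str, float] = field(default_factory=dict)

    @property
    def urban_area_km2(self) -> float:
        return self.cells.shape[0] * (CELL_SIZE_M / 1000.0) ** 2

    def cell_centers(self) -> np.ndarray:
        return (np.asarray(self.cells, dtype=float) + 0.5) * CELL_SIZE_M


@dataclass
class Landscape:
    areas: list[AreaLandscape]

    def destinations_of(self, cls: str) -> np.ndarray:
        pts = [a.destinations.get(cls, np.zeros((0, 2))) for a in self.areas]
        pts = [p for p in pts if len(p)]
        return np.vstack(pts) if pts else np.zeros((0, 2))

    def to_dict(self) -> dict:
        return {
            "areas": [
                {
                    "area_id": a.area_id,
                    "cells": np.asarray(a.cells).tolist(),
                    "destinations": {
                        k: np.asarray(v).tolist() for k, v in a.destinations.items()
                    },
                    "intersections": np.asarray(a.intersections).tolist(),
                    "population": int(a.population),
                    "floor_areas": {k: float(v) for k, v in a.floor_areas.items()},
                }
                for a in self.areas
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landscape":
        areas = [
            AreaLandscape(
                area_id=a["area_id"],
                cells=np.asarray(a["cells"], dtype=int).reshape(-1, 2),
                destinations={
                    k: np.asarray(v, dtype=float).reshape(-1, 2)
                    for k, v in a["destinations"].items()
                },
                intersections=np.asarray(a["intersections"], dtype=float).reshape(-1, 2),
                population=a["population"],
                floor_areas=a["floor_areas"],
            )
            for a in d["areas"]
        ]
        return cls(areas=areas)


def mean_grid_distance(area: AreaLandscape, destinations: np.ndarray) -> float:
    """Mean Euclidean distance (m) from each urbanized cell centre to its
    nearest destination point (destinations may lie outside the area)."""
    if area.cells.shape[0] == 0:
        raise ValueError(f"area {area.area_id!r} has no urbanized cells")
    destinations = np.asarray(destinations, dtype=float).reshape(-1, 2)
    if destinations.shape[0] == 0:
        raise ValueError("no destinations exist anywhere")
    tree = cKDTree(destinations)
    dists, _ = tree.query(area.cell_centers())
    return float(np.mean(dists))


def density(count: float, urban_area_km2: float) -> float:
    """Events per km^2 of urbanized land."""
    if urban_area_km2 <= 0:
        raise ValueError("urbanized area must be positive")
    return count / urban_area_km2


def land_use_mix(floor_areas: Mapping[str, float]) -> float:
    """Entropy index -sum(p_k ln p_k)/ln(K) over the K=3 floor-area classes.

    0 = a single land use, 1 = perfectly even mix; zero-share classes
    contribute nothing to the sum.
    """
    vals = np.array([float(floor_areas.get(c, 0.0)) for c in FLOOR_CLASSES])
    if np.any(vals < 0):
        raise ValueError("floor areas must be nonnegative")
    total = vals.sum()
    if total == 0:
        raise ValueError("all floor areas are zero; LUM undefined")
    p = vals / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(FLOOR_CLASSES)) + 0.0)


def tertile_categorize(
    values: Sequence[float] | pd.Series,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Assign T1/T2/T3 by cutting at the 33.3rd and 66.7th percentiles.

    Cut points use linear-interpolation percentiles; a value tied exactly
    with a cut point goes to the lower tertile.  ``weights`` (e.g. area
    populations) switches to weighted percentiles so tertiles balance
    persons instead of areas.
    """
    vals = np.asarray(values, dtype=float)
    if np.unique(vals).size < 3:
        raise ValueError("need at least 3 distinct values to form tertiles")
    if weights is None:
        q1, q2 = np.percentile(vals, [100 / 3, 200 / 3])
    else:
        w = np.asarray(weights, dtype=float)
        order = np.argsort(vals)
        cw = np.cumsum(w[order]) - 0.5 * w[order]
        cw /= np.sum(w)
        q1, q2 = np.interp([1 / 3, 2 / 3], cw, vals[order])
    codes = 1 + (vals > q1).astype(int) + (vals > q2).astype(int)
    return np.array([f"T{c}" for c in codes])


def compute_metric_table(landscape: Landscape) -> pd.DataFrame:
    """Per-area raw metrics plus tertile labels, indexed by area_id.

    Columns: dist_pa_m, dist_park_m, dist_transit_m, pop_density,
    intersection_density, lum, and a ``<metric>_tertile`` for each.
    """
    dest_trees = {c: landscape.destinations_of(c) for c in DESTINATION_CLASSES}
    rows = {}
    for a in landscape.areas:
        rows[a.area_id] = {
            "dist_pa_m": mean_grid_distance(a, dest_trees["pa_facility"]),
            "dist_park_m": mean_grid_distance(a, dest_trees["park"]),
            "dist_transit_m": mean_grid_distance(a, dest_trees["transit"]),
            "pop_density": density(a.population, a.urban_area_km2),
            "intersection_density": density(len(a.intersections), a.urban_area_km2),
            "lum": land_use_mix(a.floor_areas),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "area_id"
    for col in list(df.columns):
        df[f"{col}_tertile"] = tertile_categorize(df[col])
    return df
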