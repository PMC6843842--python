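"""Synthetic landscapes and nested cohorts with known ground truth.

The cohort generator runs the model forward: an intrinsic CAR field u (sum
to zero per graph component) and iid Normal effects v on the logit scale,
categorical covariates drawn from declared level probabilities, and
Bernoulli outcomes.  Defaults emulate the study conditions the package
targets: 546 areas with on average ~143 adults each and ~25% outcome
prevalence.  All randomness flows from a single master seed through
``numpy`` SeedSequence spawning, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CovariateSchema, MultilevelDataset
from .model_core import probabilities
from .neighborhood_metrics import (
    AreaLandscape,
    DESTINATION_CLASSES,
    FLOOR_CLASSES,
    Landscape,
)
from .spatial_graph import AreaGraph, build_graph, sample_car

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "lattice_graph",
    "simulate_cohort",
    "simulate_landscape",
]


def lattice_graph(n_areas: int) -> AreaGraph:
    """Rook-adjacency rectangular lattice nearest to square with n_areas
    nodes (the last row may be partial; the graph stays connected)."""
    if n_areas < 1:
        raise ValueError("need at least one area")
    ncol = max(int(round(np.sqrt(n_areas))), 1)
    ids = [f"A{i:04d}" for i in range(n_areas)]
    edges = []
    for i in range(n_areas):
        r, c = divmod(i, ncol)
        if c + 1 < ncol and i + 1 < n_areas:
            edges.append((ids[i], ids[i + 1]))
        if i + ncol < n_areas:
            edges.append((ids[i], ids[i + ncol]))
    return build_graph(edges, ids)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for the forward simulation.

    ``covariate_probs`` maps covariate -> {level: probability}; ``beta`` and
    ``gamma`` map dummy-column labels (``"cov[level]"``) to true log-odds
    effects.  ``area_covariate_probs`` generates area-level categorical
    covariates (e.g. tertiles).  Mean area size is negative-binomially
    dispersed (``size_dispersion`` is the NB shape; larger = less spread),
    reflecting how widely district populations vary.
    """

    n_areas: int = 546
    mean_individuals: float = 143.0
    size_dispersion: float = 5.0
    alpha: float = -1.1
    beta: Mapping[str, float] = field(default_factory=dict)
    gamma: Mapping[str, float] = field(default_factory=dict)
    sigma_u2: float = 0.5
    sigma_v2: float = 0.1
    covariate_probs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    area_covariate_probs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    edges: Sequence[tuple[str, str]] | None = None
    seed: int = 0

    def implied_prevalence(self) -> float:
        """Rough marginal prevalence at covariate reference levels (logit
        alpha, random effects averaged out by simulation, reported for
        orientation only)."""
        return float(1.0 / (1.0 + np.exp(-self.alpha)))


@dataclass
class SimulatedTruth:
    config: SimulationConfig
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray  # per-individual outcome probability

    def sf_proxy(self) -> float:
        """Realized var(u) / (var(u) + var(v)) of the drawn effect vectors."""
        vu, vv = float(np.var(self.u)), float(np.var(self.v))
        return vu / (vu + vv) if (vu + vv) > 0 else np.nan


def _sample_levels(
    rng: np.random.Generator, probs: Mapping[str, float], n: int
) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[lv] for lv in levels], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError(f"level probabilities must be nonnegative and sum to 1: {probs}")
    return rng.choice(levels, size=n, p=p / p.sum())


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[MultilevelDataset, AreaGraph, SimulatedTruth]:
    """Generate (dataset, graph, truth) by running the model forward."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_sizes, rng_u, rng_v, rng_cov, rng_y = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    if cfg.edges is not None:
        ids = sorted({a for e in cfg.edges for a in e})
        if len(ids) != cfg.n_areas:
            raise ValueError("edge list does not cover n_areas ids")
        graph = build_graph(cfg.edges, ids)
    else:
        graph = lattice_graph(cfg.n_areas)
    ids = graph.area_ids

    # per-area sizes: NB around the mean, at least 1 resident per area
    if cfg.mean_individuals <= 0:
        raise ValueError("mean_individuals must be positive")
    shape = cfg.size_dispersion
    p_nb = shape / (shape + cfg.mean_individuals)
    sizes = np.maximum(rng_sizes.negative_binomial(shape, p_nb, cfg.n_areas), 1)

    u = (
        sample_car(graph, cfg.sigma_u2, rng_u)
        if cfg.sigma_u2 > 0
        else np.zeros(cfg.n_areas)
    )
    v = rng_v.normal(0.0, np.sqrt(cfg.sigma_v2), cfg.n_areas)

    area_col = np.repeat(ids, sizes)
    area_idx = np.repeat(np.arange(cfg.n_areas), sizes)
    n = int(sizes.sum())

    lam = cfg.alpha + u[area_idx] + v[area_idx]
    data: dict[str, np.ndarray] = {"area_id": area_col}
    schema_levels: dict[str, list[str]] = {}
    for cov, probs in cfg.covariate_probs.items():
        draws = _sample_levels(rng_cov, probs, n)
        data[cov] = draws
        schema_levels[cov] = list(probs)
        for lv in probs:
            eff = cfg.beta.get(f"{cov}[{lv}]", 0.0)
            if eff:
                lam += eff * (draws == lv)

    # area-level categorical covariates, constant within area
    area_rows: dict[str, np.ndarray] = {}
    for cov, probs in cfg.area_covariate_probs.items():
        per_area = _sample_levels(rng_cov, probs, cfg.n_areas)
        area_rows[cov] = per_area
        expanded = per_area[area_idx]
        data[cov] = expanded
        schema_levels[cov] = list(probs)
        for lv in probs:
            eff = cfg.gamma.get(f"{cov}[{lv}]", 0.0)
            if eff:
                lam += eff * (expanded == lv)

    p = probabilities(lam)
    y = rng_y.binomial(1, p)
    data_out = {"area_id": data["area_id"], "outcome": y}
    data_out.update({k: v_ for k, v_ in data.items() if k != "area_id"})
    df = pd.DataFrame(data_out)

    # individual-level covariates go in the schema; area-level ones live in
    # the per-area table (their expanded copies in df are convenience columns)
    indiv_levels = {k: v_ for k, v_ in schema_levels.items() if k not in area_rows}
    schema = CovariateSchema(levels=indiv_levels)
    area_cov_df = (
        pd.DataFrame(area_rows, index=pd.Index(ids, name="area_id"))
        if area_rows
        else None
    )
    ds = MultilevelDataset(
        individuals=df, schema=schema, areas=list(ids), area_covariates=area_cov_df
    )
    truth = SimulatedTruth(config=cfg, u=u, v=v, p=p)
    return ds, graph, truth


@dataclass(frozen=True)
class LandscapeConfig:
    """Controls for the synthetic landscape generator.

    ``destination_intensity`` is the expected number of destinations per
    area and class; ``dirichlet_concentration`` shapes the floor-area mix
    (large = even mix, LUM near 1; small = single-use, LUM near 0).
    Default scales are chosen so metric distributions span the plausible
    ranges of district-level walkability tables (hundreds of metres to a
    few kilometres for distances, LUM across (0, 1)).
    """

    n_areas: int = 25
    cells_per_side: int = 10  # each area is a cells_per_side^2 block of 100 m cells
    destination_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"pa_facility": 0.7, "park": 1.5, "transit": 6.0}
    )
    intersection_intensity: float = 15.0
    mean_population: float = 4000.0
    dirichlet_concentration: float = 1.0
    total_floor_area_m2: float = 5e5
    seed: int = 0


def simulate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Rectangular per-area cell blocks on a square super-grid, destinations
    and intersections from seeded Poisson point processes, Dirichlet floor-
    area mixtures so LUM spans (0, 1)."""
    if any(v < 0 for v in cfg.destination_intensity.values()):
        raise ValueError("destination intensities must be nonnegative")
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss)
    ncol = max(int(np.ceil(np.sqrt(cfg.n_areas))), 1)
    side_m = cfg.cells_per_side * 100.0
    areas = []
    for i in range(cfg.n_areas):
        r, c = divmod(i, ncol)
        x0, y0 = c * side_m, r * side_m
        cells = np.array(
            [
                (c * cfg.cells_per_side + ix, r * cfg.cells_per_side + iy)
                for ix in range(cfg.cells_per_side)
                for iy in range(cfg.cells_per_side)
            ],
            dtype=int,
        )
        destinations = {}
        for klass in DESTINATION_CLASSES:
            lam_d = cfg.destination_intensity.get(klass, 0.0)
            k = rng.poisson(lam_d)
            destinations[klass] = (
                np.column_stack(
                    [x0 + rng.uniform(0, side_m, k), y0 + rng.uniform(0, side_m, k)]
                )
                if k
                else np.zeros((0, 2))
            )
        k = rng.poisson(cfg.intersection_intensity)
        intersections = np.column_stack(
            [x0 + rng.uniform(0, side_m, k), y0 + rng.uniform(0, side_m, k)]
        )
        mix = rng.dirichlet([cfg.dirichlet_concentration] * len(FLOOR_CLASSES))
        floor = dict(zip(FLOOR_CLASSES, mix * cfg.total_floor_area_m2))
        areas.append(
            AreaLandscape(
                area_id=f"A{i:04d}",
                cells=cells,
                destinations=destinations,
                intersections=intersections,
                population=int(rng.poisson(cfg.mean_population)),
                floor_areas=floor,
            )
        )
    return Landscape(areas=areas)
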