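"""Areal adjacency and the intrinsic conditional autoregressive (CAR) prior.

The intrinsic CAR on an area graph specifies each area effect conditionally
as Normal(mean of neighbours' effects, sigma_u^2 / neighbour count).  The
joint density is the improper Gaussian exp(-u' Q u / (2 sigma_u^2)) with
precision pattern Q_ii = w_i+, Q_ik = -w_ik; Q is singular with one null
vector (the constant) per connected component, so sampling is done on the
sum-to-zero subspace of each component via the spectral decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "AreaGraph",
    "GraphError",
    "IslandError",
    "build_graph",
    "read_edge_list",
    "car_precision",
    "car_conditional",
    "sample_car",
]


class GraphError(ValueError):
    """Invalid adjacency input (self-loop, unknown id)."""


class IslandError(ValueError):
    """The CAR full conditional is undefined for an area with no neighbours."""


@dataclass
class AreaGraph:
    """Symmetric adjacency over N areas, indexed 0..N-1.

    ``edges`` holds unordered index pairs (i < k); w_ik = 1 iff the pair is
    present.  ``neighbor_counts`` is the vector w_i+.
    """

    n_areas: int
    edges: frozenset[tuple[int, int]]
    area_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, k in self.edges:
            if i == k:
                raise GraphError(f"self-loop at area index {i}")
            if not (0 <= i < self.n_areas and 0 <= k < self.n_areas):
                raise GraphError(f"edge ({i},{k}) out of range for N={self.n_areas}")
        if not self.area_ids:
            self.area_ids = [str(i) for i in range(self.n_areas)]
        counts = np.zeros(self.n_areas, dtype=np.int64)
        nbrs: list[list[int]] = [[] for _ in range(self.n_areas)]
        for i, k in self.edges:
            counts[i] += 1
            counts[k] += 1
            nbrs[i].append(k)
            nbrs[k].append(i)
        self.neighbor_counts = counts
        self.neighbors = [sorted(v) for v in nbrs]

    @property
    def islands(self) -> list[int]:
        return [i for i in range(self.n_areas) if self.neighbor_counts[i] == 0]

    def components(self) -> list[list[int]]:
        """Connected components as sorted index lists (islands included)."""
        g = self.to_networkx()
        return [sorted(c) for c in nx.connected_components(g)]

    @property
    def n_components(self) -> int:
        return len(self.components())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    def coloring(self) -> list[np.ndarray]:
        """Partition of indices into independent sets (no two adjacent).

        Used by the Gibbs-style blocked Metropolis update of the CAR field:
        areas in one colour class have disjoint neighbourhoods, so their
        full conditionals do not involve each other and can be updated
        simultaneously.
        """
        col = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(col.values(), default=0) + 1
        return [
            np.array(sorted(i for i, c in col.items() if c == cc), dtype=np.int64)
            for cc in range(k)
        ]


def build_graph(
    edge_list: Iterable[tuple[str, str]], areas: Sequence[str]
) -> AreaGraph:
    """Build an AreaGraph from id pairs; symmetric closure, duplicates collapsed."""
    pos = {a: i for i, a in enumerate(areas)}
    if len(pos) != len(areas):
        raise GraphError("duplicate area ids")
    edges = set()
    for a, b in edge_list:
        if a not in pos or b not in pos:
            raise GraphError(f"edge references unknown area id: ({a!r}, {b!r})")
        i, k = pos[a], pos[b]
        if i == k:
            raise GraphError(f"self-loop at area {a!r}")
        edges.add((min(i, k), max(i, k)))
    return AreaGraph(n_areas=len(areas), edges=frozenset(edges), area_ids=list(areas))


def read_edge_list(path: str | Path, areas: Sequence[str]) -> AreaGraph:
    """Read edges.csv (area_id_a, area_id_b) or a GAL neighbour file."""
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise GraphError(f"empty adjacency file {path}")
    first = text[0].split(",")
    if len(first) >= 2 and not text[0].lstrip()[0].isdigit():
        # CSV with header
        import pandas as pd

        df = pd.read_csv(path, dtype=str)
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return build_graph(pairs, areas)
    # GAL format: header line "n", then per area a line "id count" + a line of neighbour ids
    lines = [ln.split() for ln in text]
    pairs = []
    j = 1
    while j < len(lines):
        area, cnt = lines[j][0], int(lines[j][1])
        if cnt > 0:
            for nb in lines[j + 1]:
                pairs.append((area, nb))
            j += 2
        else:
            j += 1
    return build_graph(pairs, areas)


def car_precision(graph: AreaGraph) -> sp.csr_matrix:
    """Sparse intrinsic-CAR precision pattern Q (unit variance scale).

    Q = D - A with D = diag(w_i+): symmetric, zero row sums,
    rank N - (number of connected components).
    """
    n = graph.n_areas
    if not graph.edges:
        return sp.csr_matrix((n, n))
    rows, cols, vals = [], [], []
    for i, k in graph.edges:
        rows += [i, k]
        cols += [k, i]
        vals += [-1.0, -1.0]
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    d = sp.diags(graph.neighbor_counts.astype(float))
    return (d + a).tocsr()


def car_conditional(
    u: np.ndarray, i: int, sigma_u2: float, graph: AreaGraph
) -> tuple[float, float]:
    """Full-conditional mean and variance of u_i given its neighbours.

    mean = average of neighbouring effects, variance = sigma_u^2 / w_i+.
    Undefined for islands (no neighbours).
    """
    w_plus = int(graph.neighbor_counts[i])
    if w_plus == 0:
        raise IslandError(f"area index {i} has no neighbours; CAR conditional undefined")
    nbrs = graph.neighbors[i]
    return float(np.mean(u[nbrs])), float(sigma_u2 / w_plus)


def sample_car(
    graph: AreaGraph,
    sigma_u2: float,
    rng: np.random.Generator | int,
    islands: str = "zero",
) -> np.ndarray:
    """Draw one intrinsic-CAR vector constrained to sum to zero per component.

    The draw has covariance sigma_u^2 * Q^+ (Moore-Penrose generalized
    inverse), realised per connected component through the eigenvectors of Q
    with positive eigenvalue.  Islands get u = 0 (``islands="zero"``, the
    usual BYM convention); ``islands="component"`` keeps them as their own
    sum-to-zero component, which for a singleton is also 0 — the flag exists
    so multi-island variants stay explicit at call sites.
    """
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = graph.n_areas
    u = np.zeros(n)
    if sigma_u2 == 0:
        return u
    if islands not in ("zero", "component"):
        raise ValueError(f"unknown island policy {islands!r}")
    q = car_precision(graph).toarray()
    for comp in graph.components():
        if len(comp) == 1:
            continue  # island: u stays 0 under either policy
        qc = q[np.ix_(comp, comp)]
        evals, evecs = np.linalg.eigh(qc)
        keep = evals > 1e-10 * evals[-1]
        z = rng.standard_normal(int(keep.sum()))
        draw = evecs[:, keep] @ (z / np.sqrt(evals[keep]))
        u[comp] = np.sqrt(sigma_u2) * draw
    return u
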