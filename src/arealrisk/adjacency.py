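"""First-order contiguity structure over areal units.

The same neighbour definition feeds both the Moran screen and the
intrinsic CAR prior: binary symmetric weights w_ij in {0,1} with no
self-loops.  Queen contiguity (any shared boundary point) is the
default rule for irregular administrative polygons; rook (shared edge
of positive length) is available by flag.  Areas with no neighbours
are flagged as islands and kept, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.strtree import STRtree

from .geometry import PolygonLayer


@dataclass
class Adjacency:
    """Symmetric neighbour sets over an ordered list of area IDs."""

    ids: list[str]
    neighbors: dict[str, set[str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {a: k for k, a in enumerate(self.ids)}
        for a in self.ids:
            self.neighbors.setdefault(a, set())

    @property
    def n(self) -> int:
        return len(self.ids)

    def degree(self, area_id: str) -> int:
        return len(self.neighbors[area_id])

    def islands(self) -> list[str]:
        return [a for a in self.ids if not self.neighbors[a]]

    def edges(self) -> list[tuple[str, str]]:
        """Unique undirected edges, each once, ordered by area index."""
        out = []
        for a in self.ids:
            ia = self._index[a]
            for b in self.neighbors[a]:
                if self._index[b] > ia:
                    out.append((a, b))
        return out

    def to_sparse(self) -> sp.csr_matrix:
        """Binary symmetric weight matrix in the order of ``ids``."""
        rows, cols = [], []
        for a, b in self.edges():
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def subgraph(self, keep: list[str]) -> "Adjacency":
        keep_set = set(keep)
        nb = {a: self.neighbors[a] & keep_set for a in keep}
        return Adjacency(list(keep), nb)

    def components(self) -> list[list[str]]:
        """Connected components as lists of area IDs (islands are singletons)."""
        ncomp, labels = connected_components(self.to_sparse(), directed=False)
        out: list[list[str]] = [[] for _ in range(ncomp)]
        for a, lab in zip(self.ids, labels):
            out[lab].append(a)
        return out

    def graph_ball(self, center: str, radius: int) -> set[str]:
        """All areas within ``radius`` graph hops of ``center`` (inclusive)."""
        frontier = {center}
        ball = {center}
        for _ in range(radius):
            frontier = {b for a in frontier for b in self.neighbors[a]} - ball
            ball |= frontier
        return ball

    def greedy_coloring(self) -> np.ndarray:
        """Proper vertex colouring (deterministic, by area index order).

        Used to schedule conditionally independent block updates in the
        CAR sampler: no two neighbours share a colour.
        """
        colors = np.full(self.n, -1, dtype=int)
        for i, a in enumerate(self.ids):
            taken = {colors[self._index[b]] for b in self.neighbors[a]}
            c = 0
            while c in taken:
                c += 1
            colors[i] = c
        return colors


def build_adjacency(layer: PolygonLayer, rule: str = "queen") -> Adjacency:
    """Derive first-order contiguity from a polygon layer.

    ``queen``: neighbours share at least one boundary point.
    ``rook``: neighbours share a boundary segment of positive length.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule: {rule!r}")
    if len(set(layer.ids)) != len(layer.ids):
        raise ValueError("duplicate area IDs in polygon layer")
    for a, g in layer:
        if g.is_empty or not g.is_valid:
            raise ValueError(f"invalid or empty geometry for area {a!r}")

    tree = STRtree(layer.geoms)
    neighbors: dict[str, set[str]] = {a: set() for a in layer.ids}
    for i, (a, g) in enumerate(layer):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j == i:
                continue
            inter = g.intersection(layer.geoms[j])
            if inter.is_empty:
                continue
            # dimension 0 = touch at points only; 1 = shared segment
            if rule == "queen" or inter.length > 0:
                b = layer.ids[j]
                neighbors[a].add(b)
                neighbors[b].add(a)
    return Adjacency(list(layer.ids), neighbors)


def row_standardized_weights(adj: Adjacency) -> sp.csr_matrix:
    """Row-standardized weights w'_ij = w_ij / |N(i)|; island rows all zero."""
    w = adj.to_sparse().tolil()
    for i, a in enumerate(adj.ids):
        d = adj.degree(a)
        if d > 0:
            w[i, :] = w[i, :] / d
    return w.tocsr()


@dataclass
class AdjacencyReport:
    symmetry_violations: list[tuple[str, str]]
    self_loops: list[str]
    islands: list[str]
    n_components: int
    components: list[list[str]]

    @property
    def ok(self) -> bool:
        return not self.symmetry_violations and not self.self_loops


def validate_adjacency(adj: Adjacency) -> AdjacencyReport:
    """Check symmetry and self-loop invariants; report islands and components."""
    sym, loops = [], []
    for a in adj.ids:
        for b in adj.neighbors[a]:
            if b == a:
                loops.append(a)
            elif a not in adj.neighbors.get(b, set()):
                sym.append((a, b))
    comps = adj.components()
    return AdjacencyReport(sym, loops, adj.islands(), len(comps), comps)


def write_edge_list(adj: Adjacency, path) -> None:
    """Adjacency as an edge-list CSV (area_i, area_j), each edge once."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["area_i", "area_j"])
        w.writerows(adj.edges())
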