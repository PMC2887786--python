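"""Shared fixtures: regular lattices, small synthetic studies, oracles."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from arealrisk.adjacency import Adjacency, build_adjacency
from arealrisk.geometry import PolygonLayer


def grid_layer(nx: int, ny: int) -> PolygonLayer:
    """nx x ny lattice of unit squares, IDs G<col><row> zero-padded."""
    ids, geoms = [], []
    for i in range(nx):
        for j in range(ny):
            ids.append(f"G{i:02d}{j:02d}")
            geoms.append(box(i, j, i + 1, j + 1))
    return PolygonLayer(ids, geoms)


def lattice_adjacency(nx: int, ny: int, rule: str = "queen") -> Adjacency:
    return build_adjacency(grid_layer(nx, ny), rule=rule)


def morans_i_bruteforce(values, w_dense) -> float:
    """Independent O(n^2) double-loop Moran's I oracle."""
    x = np.asarray(values, dtype=float)
    n = x.size
    z = x - x.mean()
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += w_dense[i, j]
            num += w_dense[i, j] * z[i] * z[j]
    return (n / s0) * num / float((z * z).sum())


def lattice_centroids_helper(nx: int, ny: int) -> np.ndarray:
    return np.array([(i + 0.5, j + 0.5) for i in range(nx) for j in range(ny)])


@pytest.fixture(scope="session")
def lattice10() -> Adjacency:
    return lattice_adjacency(10, 10)


@pytest.fixture(scope="session")
def layer10() -> PolygonLayer:
    return grid_layer(10, 10)
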