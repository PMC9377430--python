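"""Areal geographies: region identifiers plus a symmetric neighbor structure.

A :class:`Geography` is the backbone shared by the spatial statistics
(Moran's I) and the intrinsic-CAR spatial prior: an ordered list of region
ids and, for each region, the indices of its contiguity neighbors.
Synthetic studies use regular lattices with rook or queen contiguity;
real studies can load an arbitrary edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Geography", "generate_lattice", "read_edge_list", "write_edge_list"]


class InvalidGeometryError(ValueError):
    """Raised when a geography cannot support a neighbor structure."""


@dataclass(frozen=True)
class Geography:
    """Regions with a symmetric adjacency structure.

    Parameters
    ----------
    region_ids : list of str
        Ordered region identifiers; index in this list is the canonical
        region index used everywhere downstream.
    adjacency : tuple of tuple of int
        ``adjacency[i]`` holds the neighbor indices of region ``i``.
        Must be symmetric and free of self-loops.
    coords : optional array of shape (n, 2)
        ``(row, col)`` cell coordinates for lattice geometries; used only
        for plotting and polygon export.
    """

    region_ids: tuple
    adjacency: tuple
    coords: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        n = len(self.region_ids)
        if len(self.adjacency) != n:
            raise InvalidGeometryError("adjacency length must match region count")
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if j == i:
                    raise InvalidGeometryError(f"region {i} is its own neighbor")
                if not (0 <= j < n):
                    raise InvalidGeometryError(f"neighbor index {j} out of range")
                if i not in self.adjacency[j]:
                    raise InvalidGeometryError(
                        f"adjacency is not symmetric: {i}->{j} but not {j}->{i}"
                    )
        islands = self.islands
        if islands:
            logger.warning("geography contains %d island region(s): %s",
                           len(islands), islands[:10])

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def islands(self) -> list:
        """Indices of regions with no neighbors."""
        return [i for i, nbrs in enumerate(self.adjacency) if len(nbrs) == 0]

    @property
    def edges(self) -> np.ndarray:
        """Unordered neighbor pairs as an array of shape (n_edges, 2), i < j."""
        out = [(i, j) for i, nbrs in enumerate(self.adjacency) for j in nbrs if i < j]
        return np.asarray(out, dtype=np.intp).reshape(-1, 2)

    def degree(self) -> np.ndarray:
        return np.asarray([len(nbrs) for nbrs in self.adjacency], dtype=np.intp)


def generate_lattice(n_rows: int, n_cols: int, contiguity: str = "rook") -> Geography:
    """Regular grid geography with rook (default) or queen contiguity.

    Region ids are ``"r{row}c{col}"`` in row-major order.  Raises
    :class:`InvalidGeometryError` when the grid has fewer than two cells,
    since no neighbor relation is then possible.
    """
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 2:
        raise InvalidGeometryError(
            f"a {n_rows}x{n_cols} grid cannot host a neighbor structure"
        )
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity {contiguity!r}")
    if contiguity == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]

    def idx(r, c):
        return r * n_cols + c

    adjacency = []
    coords = np.empty((n_rows * n_cols, 2), dtype=np.intp)
    ids = []
    for r in range(n_rows):
        for c in range(n_cols):
            nbrs = tuple(sorted(
                idx(r + dr, c + dc)
                for dr, dc in offsets
                if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
            ))
            adjacency.append(nbrs)
            coords[idx(r, c)] = (r, c)
            ids.append(f"r{r}c{c}")
    return Geography(tuple(ids), tuple(adjacency), coords)


def write_edge_list(geog: Geography, path) -> None:
    """Persist adjacency as a two-column CSV of region-id pairs (i < j)."""
    e = geog.edges
    df = pd.DataFrame({
        "region_a": [geog.region_ids[i] for i in e[:, 0]],
        "region_b": [geog.region_ids[j] for j in e[:, 1]],
    })
    df.to_csv(path, index=False)


def read_edge_list(path, region_ids=None) -> Geography:
    """Build a :class:`Geography` from a two-column edge-list CSV.

    When ``region_ids`` is omitted, regions are the sorted union of ids
    appearing in the file (an id never appearing cannot be represented —
    pass ``region_ids`` explicitly to include islands).
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    a, b = df.iloc[:, 0], df.iloc[:, 1]
    if region_ids is None:
        region_ids = sorted(set(a) | set(b))
    pos = {rid: i for i, rid in enumerate(region_ids)}
    nbrs = [set() for _ in region_ids]
    for x, y in zip(a, b):
        i, j = pos[x], pos[y]
        if i != j:
            nbrs[i].add(j)
            nbrs[j].add(i)
    return Geography(tuple(region_ids), tuple(tuple(sorted(s)) for s in nbrs))
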