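"""Spatial graphs on a single tissue region.

Three neighbor notions coexist, deliberately on two different metrics:

* **Contacts** — border-to-border: two cells are in contact when the distance
  between their outer membranes is at most a threshold (default 6 um, the
  histoCAT convention). With tabular input the membrane is approximated by a
  disc of each cell's equivalent radius, so the border distance is
  ``max(0, ||c_i - c_j|| - r_i - r_j)``.
* **k-nearest neighbors within a radius** — center-to-center: for cellular
  neighborhood features, each index cell collects up to k nearest cells
  (default 10) no farther than r (default 40 um) from its centroid.
* **Delaunay edges** — center-to-center triangulation, used as a diagnostic
  of typical inter-cell spacing (which motivates the 40 um radius).

All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from spatialtme.core_io import DEFAULT_CELL_RADIUS_UM

__all__ = [
    "AdjacencyList",
    "NeighborSets",
    "SpatialGraph",
    "contact_pairs",
    "delaunay_graph",
    "knn_within_radius",
    "neighbor_distance_stats",
]


@dataclass
class AdjacencyList:
    """Unordered cell-cell contacts for one region.

    ``pairs`` holds index pairs (positions into the region's cell table, with
    ``i < j``) and ``border_um`` the corresponding membrane distances;
    ``cell_ids`` maps positions back to cell identifiers.
    """

    roi_id: object
    pairs: np.ndarray  # (E, 2) int
    border_um: np.ndarray  # (E,) float
    cell_ids: np.ndarray  # (n,) original identifiers
    threshold_um: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_a": self.cell_ids[self.pairs[:, 0]] if len(self.pairs) else [],
                "cell_b": self.cell_ids[self.pairs[:, 1]] if len(self.pairs) else [],
                "border_um": self.border_um,
            }
        )


@dataclass
class NeighborSets:
    """Per-cell nearest-neighbor lists (positions), distance-sorted.

    ``neighbors[i]`` lists positions of up to k cells within radius r of cell
    i, ascending by center distance; ``distances[i]`` is parallel.
    """

    neighbors: list[np.ndarray]
    distances: list[np.ndarray]
    cell_ids: np.ndarray
    k: int
    radius_um: float


@dataclass
class SpatialGraph:
    """Delaunay neighbor graph: edges between triangulated cell centroids."""

    edges: np.ndarray  # (E, 2) int positions, i < j
    distances: np.ndarray  # (E,) center distances
    cell_ids: np.ndarray


def _coords(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_um", "y_um"]].to_numpy(dtype=float)


def _radii(cells: pd.DataFrame, default_radius: float) -> np.ndarray:
    if "radius_um" in cells.columns:
        return cells["radius_um"].astype(float).fillna(default_radius).to_numpy()
    return np.full(len(cells), float(default_radius))


def contact_pairs(
    cells: pd.DataFrame,
    threshold_um: float = 6.0,
    default_radius: float = DEFAULT_CELL_RADIUS_UM,
    roi_id: object = None,
) -> AdjacencyList:
    """Find all cell pairs whose border distance is <= ``threshold_um``.

    The border distance is floored at zero for overlapping discs, so
    overlapping cells always count as in contact.
    """
    if threshold_um < 0:
        raise ValueError("contact threshold must be nonnegative")
    if len(cells) == 0:
        raise ValueError("contact_pairs requires a nonempty region")
    xy = _coords(cells)
    radii = _radii(cells, default_radius)
    if roi_id is None and "roi_id" in cells.columns and len(cells):
        roi_id = cells["roi_id"].iloc[0]

    # Candidate search radius covers the largest possible touching pair.
    search_r = threshold_um + 2.0 * float(radii.max(initial=default_radius))
    tree = cKDTree(xy)
    cand = tree.query_pairs(search_r, output_type="ndarray")
    if len(cand) == 0:
        pairs = np.empty((0, 2), dtype=np.intp)
        border = np.empty(0, dtype=float)
    else:
        d = np.linalg.norm(xy[cand[:, 0]] - xy[cand[:, 1]], axis=1)
        border = np.maximum(0.0, d - radii[cand[:, 0]] - radii[cand[:, 1]])
        keep = border <= threshold_um
        pairs = np.sort(cand[keep], axis=1)
        border = border[keep]
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, border = pairs[order], border[order]
    return AdjacencyList(
        roi_id=roi_id,
        pairs=pairs.astype(np.intp),
        border_um=border,
        cell_ids=cells["cell_id"].to_numpy() if "cell_id" in cells.columns else np.arange(len(cells)),
        threshold_um=float(threshold_um),
    )


def delaunay_graph(cells: pd.DataFrame) -> SpatialGraph:
    """Delaunay triangulation edge set over cell centroids.

    Degenerate inputs fall back deterministically: fewer than 3 points give
    the complete graph; collinear points give the chain along the line.
    """
    xy = _coords(cells)
    n = len(xy)
    cell_ids = (
        cells["cell_id"].to_numpy() if "cell_id" in cells.columns else np.arange(n)
    )
    if n < 2:
        return SpatialGraph(
            edges=np.empty((0, 2), dtype=np.intp),
            distances=np.empty(0),
            cell_ids=cell_ids,
        )
    if n < 3:
        edges = np.array([[0, 1]], dtype=np.intp)
    else:
        try:
            tri = Delaunay(xy)
            pair_set = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        pair_set.add((i, j))
            edges = np.array(sorted(pair_set), dtype=np.intp)
        except Exception:
            # All-collinear: chain the points in order along the line.
            order = np.lexsort((xy[:, 1], xy[:, 0]))
            edges = np.sort(np.column_stack([order[:-1], order[1:]]), axis=1)
            edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))].astype(np.intp)
    d = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
    return SpatialGraph(edges=edges, distances=d, cell_ids=cell_ids)


def knn_within_radius(
    cells: pd.DataFrame,
    k: int = 10,
    radius_um: float = 40.0,
) -> NeighborSets:
    """Up to ``k`` nearest other cells per index cell, within ``radius_um``.

    Ties at the k-th distance are broken toward the smaller cell id so the
    result is deterministic regardless of input order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if len(cells) == 0:
        raise ValueError("knn_within_radius requires a nonempty region")
    xy = _coords(cells)
    n = len(xy)
    cell_ids = (
        cells["cell_id"].to_numpy() if "cell_id" in cells.columns else np.arange(n)
    )
    neighbors: list[np.ndarray] = []
    distances: list[np.ndarray] = []
    if n == 1:
        return NeighborSets([np.empty(0, np.intp)], [np.empty(0)], cell_ids, k, radius_um)

    tree = cKDTree(xy)
    # Query a few extra candidates so distance ties at the cut are visible.
    m = min(n, k + 8)
    dist, idx = tree.query(xy, k=m)
    for i in range(n):
        di, ii = dist[i], idx[i]
        mask = (ii != i) & np.isfinite(di) & (di <= radius_um)
        di, ii = di[mask], ii[mask]
        # Stable order: ascending distance, then ascending cell id.
        order = np.lexsort((cell_ids[ii], di))
        di, ii = di[order], ii[order]
        neighbors.append(ii[:k].astype(np.intp))
        distances.append(di[:k])
    return NeighborSets(neighbors, distances, cell_ids, k, float(radius_um))


def neighbor_distance_stats(graph: SpatialGraph, bin_um: float = 1.0) -> dict:
    """Histogram of Delaunay edge lengths and the modal 1-um bin.

    Returns a dict with ``bin_edges``, ``counts``, ``modal_bin`` (left edge of
    the most populated bin), and ``n_edges``. The modal spacing of real tissue
    informs the neighborhood radius choice.
    """
    if len(graph.edges) == 0:
        raise ValueError("neighbor_distance_stats requires a graph with >= 1 edge")
    d = graph.distances
    hi = np.ceil(d.max() / bin_um) * bin_um + bin_um
    edges = np.arange(0.0, hi + bin_um / 2, bin_um)
    counts, _ = np.histogram(d, bins=edges)
    modal = int(np.argmax(counts))
    return {
        "bin_edges": edges,
        "counts": counts,
        "modal_bin": float(edges[modal]),
        "n_edges": int(len(d)),
    }
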