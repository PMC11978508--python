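"""Hierarchical multiscale cell-neighborhood analysis.

From a table of cell positions and type labels, successively larger k-NN
windows are summarized as composition vectors and clustered:

* level 1 ("neighborhoods"): the cell-type composition of each cell's
  n = 10 window is clustered;
* level 2 ("communities"): the level-1 label composition over an n = 100
  window;
* level 3 ("tissue units"): the level-2 label composition over n = 300.

A window is the index cell plus its n-1 nearest neighbors (configurable).
The levels are linked in a multilevel graph whose edge weights give, for
each node, the fraction of its cells found in each next-level node — the
"line thickness" view of how cell types compose neighborhoods,
neighborhoods compose communities, and communities compose tissue units.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .distances import CellTable
from .errors import CardinalityError, WindowError

__all__ = [
    "Level",
    "MultilevelGraph",
    "NeighborhoodModel",
    "build_multilevel_graph",
    "cluster_vectors",
    "hierarchical_levels",
    "knn_composition",
]

DEFAULT_WINDOWS = (10, 100, 300)
DEFAULT_LEVEL_NAMES = ("neighborhood", "community", "tissue_unit")


def _knn_indices(positions: np.ndarray, ids: np.ndarray, n: int) -> np.ndarray:
    """Indices of each cell's window (itself + n-1 nearest neighbors).

    Distance ties are broken by cell-id order for determinism.
    """
    ncells = len(positions)
    tree = cKDTree(positions)
    k = min(n + 4, ncells)  # small slack so ties at the window edge can be re-sorted
    dists, idx = tree.query(positions, k=k)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    id_rank = np.argsort(np.argsort(ids))
    # stable sort by (distance, id-rank), then truncate to n
    order = np.lexsort((id_rank[idx], np.round(dists, 12)), axis=1)
    return np.take_along_axis(idx, order, axis=1)[:, :n]


def composition_over_labels(
    positions: np.ndarray,
    ids: np.ndarray,
    labels: np.ndarray,
    n: int,
    categories: list | None = None,
) -> tuple[np.ndarray, list]:
    """Per-cell label-frequency vectors over k-NN windows (rows sum to 1)."""
    if n > len(positions):
        raise WindowError(f"window size {n} exceeds cell count {len(positions)}")
    if n < 1:
        raise WindowError("window size must be >= 1")
    if categories is None:
        categories = sorted(set(labels.tolist()))
    cat_index = {c: i for i, c in enumerate(categories)}
    codes = np.array([cat_index[l] for l in labels.tolist()])
    windows = _knn_indices(positions, ids, n)
    mat = np.zeros((len(positions), len(categories)))
    window_codes = codes[windows]
    for j in range(len(categories)):
        mat[:, j] = (window_codes == j).sum(axis=1)
    mat /= n
    return mat, list(categories)


def knn_composition(cells: CellTable, n: int) -> tuple[np.ndarray, list[str]]:
    """Cell-type composition of each cell's n-cell window.

    Returns the (n_cells, n_types) row-stochastic matrix and the cell-type
    column order.
    """
    return composition_over_labels(cells.positions, cells.ids, cells.types, n)


def cluster_vectors(matrix: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means (k-means++ init) labels for composition vectors."""
    matrix = np.asarray(matrix, dtype=float)
    if k < 1:
        raise CardinalityError("k must be >= 1")
    if k > len(matrix):
        raise CardinalityError(f"k={k} exceeds number of observations {len(matrix)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=int(seed))
    return km.fit_predict(matrix)


@dataclass
class Level:
    name: str
    window: int
    k: int
    labels: np.ndarray           # (n_cells,) int cluster labels
    profiles: pd.DataFrame       # (k, n_categories) mean composition per cluster
    categories: list             # column order of the composition the level clustered


@dataclass
class NeighborhoodModel:
    cells: CellTable
    levels: list[Level]

    def labels_frame(self) -> pd.DataFrame:
        """Per-cell labels at every level (plus the cell type)."""
        data = {"cell_id": self.cells.ids, "cell_type": self.cells.types}
        for lvl in self.levels:
            data[lvl.name] = lvl.labels
        return pd.DataFrame(data)


def hierarchical_levels(
    cells: CellTable,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    ks: tuple[int, ...] = (8, 6, 4),
    seed: int = 0,
    level_names: tuple[str, ...] | None = None,
) -> NeighborhoodModel:
    """Fit the full neighborhood -> community -> tissue-unit hierarchy.

    Level 1 clusters cell-type compositions over the smallest window; each
    subsequent level clusters the *previous level's labels* (treated as
    categories) over its larger window. Every cell is labeled at every
    level.
    """
    if len(windows) != len(ks):
        raise ValueError("windows and ks must have equal length")
    if any(b <= a for a, b in zip(windows, windows[1:])):
        raise ValueError(f"windows must be strictly increasing, got {windows}")
    if level_names is None:
        level_names = (
            DEFAULT_LEVEL_NAMES
            if len(windows) == len(DEFAULT_LEVEL_NAMES)
            else tuple(f"level{i + 1}" for i in range(len(windows)))
        )
    for name, w in zip(level_names, windows):
        if w > len(cells):
            raise WindowError(f"level {name!r}: window {w} exceeds cell count {len(cells)}")

    levels: list[Level] = []
    current = cells.types
    for i, (name, w, k) in enumerate(zip(level_names, windows, ks)):
        mat, cats = composition_over_labels(cells.positions, cells.ids, np.asarray(current), w)
        labels = cluster_vectors(mat, k, seed=seed + i)
        prof = pd.DataFrame(
            [mat[labels == c].mean(axis=0) for c in range(k)],
            columns=[str(c) for c in cats],
            index=pd.RangeIndex(k, name="cluster"),
        )
        levels.append(Level(name=name, window=w, k=k, labels=labels, profiles=prof, categories=cats))
        current = labels.astype(str)
    return NeighborhoodModel(cells=cells, levels=levels)


@dataclass
class MultilevelGraph:
    """Directed graph linking cell types -> level-1 ... -> top level.

    Node names are ``"<level_name>:<cluster>"``; each node carries its
    level index and cell count, each edge the fraction of the lower node's
    cells found in the upper node (outgoing weights sum to 1).
    """

    graph: nx.DiGraph
    level_names: list[str]

    def nodes_frame(self) -> pd.DataFrame:
        rows = [
            {"node": n, "level": d["level"], "level_name": d["level_name"], "size": d["size"]}
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows).sort_values(["level", "node"]).reset_index(drop=True)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"lower": u, "upper": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values(["lower", "upper"]).reset_index(drop=True)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_multilevel_graph(model: NeighborhoodModel) -> MultilevelGraph:
    """Build the multilevel graph with the cell-type layer prepended as level 0.

    The edge weight from node a at level l to node b at level l+1 is the
    fraction of a's cells that carry label b at the next level.
    """
    if len(model.levels) < 2:
        raise ValueError("a multilevel graph needs at least two clustered levels")
    layer_names = ["cell_type"] + [lvl.name for lvl in model.levels]
    layer_labels = [model.cells.types.astype(str)] + [
        lvl.labels.astype(str) for lvl in model.levels
    ]
    return graph_from_layers(layer_names, layer_labels)


def graph_from_layers(layer_names: list[str], layer_labels: list[np.ndarray]) -> MultilevelGraph:
    """Multilevel graph from parallel per-cell label arrays, one per layer."""
    g = nx.DiGraph()
    for level, (name, labels) in enumerate(zip(layer_names, layer_labels)):
        values, counts = np.unique(labels, return_counts=True)
        for v, c in zip(values, counts):
            g.add_node(f"{name}:{v}", level=level, level_name=name, size=int(c))
    for level in range(len(layer_labels) - 1):
        lower, upper = layer_labels[level], layer_labels[level + 1]
        tab = pd.crosstab(pd.Series(lower, name="lower"), pd.Series(upper, name="upper"))
        for lo in tab.index:
            total = tab.loc[lo].sum()
            for up in tab.columns:
                cnt = int(tab.loc[lo, up])
                if cnt:
                    g.add_edge(
                        f"{layer_names[level]}:{lo}",
                        f"{layer_names[level + 1]}:{up}",
                        weight=cnt / total,
                        count=cnt,
                    )
    return MultilevelGraph(graph=g, level_names=layer_names)
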