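"""Cell-to-vasculature distances (VCCF-style analysis).

Given a table of cell centroids with type labels, computes for every
source cell the Euclidean distance to its nearest cell of a caller-chosen
target type set (typically endothelial cells), in 2D or 3D. The resulting
"spokes" (cell -> nearest vascular cell segments) and per-type distance
distributions are the quantitative backbone of vasculature-centered
tissue maps; rendering is left to downstream viewers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DimensionalityError, DuplicateIdError, EmptyTargetError

__all__ = [
    "CellTable",
    "DistanceResult",
    "distance_summary",
    "export_spokes",
    "nearest_target_distances",
]


@dataclass
class CellTable:
    """Cell centroids (2D or 3D, µm by default) with cell-type labels."""

    ids: np.ndarray        # (n,) str
    positions: np.ndarray  # (n, d) float, d in {2, 3}
    types: np.ndarray      # (n,) str
    units: str = "um"

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=str)
        self.positions = np.asarray(self.positions, dtype=float)
        self.types = np.asarray(self.types, dtype=str)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise DimensionalityError("positions must be (n, 2) or (n, 3)")
        if not (len(self.ids) == len(self.positions) == len(self.types)):
            raise ValueError("ids, positions and types must have equal length")
        if not np.isfinite(self.positions).all():
            raise DimensionalityError("positions contain non-finite values (mixed 2D/3D input?)")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("cell ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @classmethod
    def from_csv(cls, source, units: str = "um") -> "CellTable":
        """Read a cell table CSV (cell_id, x, y[, z], cell_type)."""
        if isinstance(source, pd.DataFrame):
            df = source
        elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            df = pd.read_csv(source)
        else:
            df = pd.read_csv(io.StringIO(str(source)))
        required = {"cell_id", "x", "y", "cell_type"}
        missing = required - set(df.columns)
        if missing:
            raise DimensionalityError(f"cell CSV missing columns: {sorted(missing)}")
        cols = ["x", "y"]
        if "z" in df.columns:
            if df["z"].isna().any() and not df["z"].isna().all():
                raise DimensionalityError("some cells have z coordinates and others do not")
            if not df["z"].isna().all():
                cols.append("z")
        return cls(
            ids=df["cell_id"].to_numpy(dtype=str),
            positions=df[cols].to_numpy(dtype=float),
            types=df["cell_type"].to_numpy(dtype=str),
            units=units,
        )

    def to_csv(self, path: str | Path | None = None) -> str:
        cols = {"cell_id": self.ids, "x": self.positions[:, 0], "y": self.positions[:, 1]}
        if self.ndim == 3:
            cols["z"] = self.positions[:, 2]
        cols["cell_type"] = self.types
        text = pd.DataFrame(cols).to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class DistanceResult:
    """Nearest-target assignment per source cell.

    ``records`` has columns source_id, source_type, target_id, distance.
    """

    records: pd.DataFrame
    target_types: frozenset[str]
    cells: CellTable = field(repr=False)
    units: str = "um"


def nearest_target_distances(
    cells: CellTable,
    target_types,
    exclude_targets_as_sources: bool = True,
) -> DistanceResult:
    """Distance from each source cell to its nearest target-type cell.

    Sources are all cells not of a target type; with
    ``exclude_targets_as_sources=False`` target cells are also sources,
    matched to their nearest *other* target (never themselves, so the
    distance is never trivially zero). Ties are broken by the
    lexicographically lowest target cell id.
    """
    target_types = frozenset(target_types)
    is_target = np.isin(cells.types, sorted(target_types))
    if not is_target.any():
        raise EmptyTargetError(f"no cells of target types {sorted(target_types)}")
    tpos = cells.positions[is_target]
    tids = cells.ids[is_target]
    # order targets by id so index 0 of a tie candidate set is the lowest id
    order = np.argsort(tids)
    tpos, tids = tpos[order], tids[order]
    tree = cKDTree(tpos)

    if exclude_targets_as_sources:
        src_mask = ~is_target
    else:
        src_mask = np.ones(len(cells), dtype=bool)
    spos = cells.positions[src_mask]
    sids = cells.ids[src_mask]
    stypes = cells.types[src_mask]
    if len(spos) == 0:
        empty = pd.DataFrame(columns=["source_id", "source_type", "target_id", "distance"])
        return DistanceResult(empty, target_types, cells, cells.units)

    src_is_target = np.isin(sids, tids)
    k = 2 if src_is_target.any() else 1
    if len(tids) == 1 and src_is_target.any():
        raise EmptyTargetError("a target source cell has no other target to match")
    dists, idx = tree.query(spos, k=max(k, 1))
    dists = np.atleast_2d(dists.T).T if dists.ndim == 1 else dists
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx

    out_tid = np.empty(len(spos), dtype=object)
    out_dist = np.empty(len(spos), dtype=float)
    for i in range(len(spos)):
        cand_d, cand_i = dists[i], idx[i]
        if src_is_target[i]:
            keep = tids[cand_i] != sids[i]
            cand_d, cand_i = cand_d[keep], cand_i[keep]
            if len(cand_i) == 0:  # self was the only neighbor returned
                d2, i2 = tree.query(spos[i], k=min(len(tids), 3))
                keep = tids[np.atleast_1d(i2)] != sids[i]
                cand_d = np.atleast_1d(d2)[keep]
                cand_i = np.atleast_1d(i2)[keep]
        d = cand_d[0]
        # resolve ties deterministically: lowest target id among equidistant
        ball = tree.query_ball_point(spos[i], d * (1 + 1e-12) + 1e-300)
        ball = [j for j in ball if tids[j] != sids[i] or not src_is_target[i]]
        ball = [j for j in ball if np.linalg.norm(tpos[j] - spos[i]) <= d + 1e-12]
        j = min(ball, key=lambda j: tids[j]) if ball else cand_i[0]
        out_tid[i] = tids[j]
        out_dist[i] = float(np.linalg.norm(tpos[j] - spos[i])) if ball else float(d)

    records = pd.DataFrame(
        {
            "source_id": sids,
            "source_type": stypes,
            "target_id": out_tid.astype(str),
            "distance": out_dist,
        }
    )
    return DistanceResult(records, target_types, cells, cells.units)


def distance_summary(result: DistanceResult) -> pd.DataFrame:
    """Per-source-type distance statistics (n, mean, median, q25, q75, max)."""
    if result.records.empty:
        return pd.DataFrame(columns=["source_type", "n", "mean", "median", "q25", "q75", "max"])
    g = result.records.groupby("source_type")["distance"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean": g.mean(),
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
            "max": g.max(),
        }
    ).reset_index()
    return out


def export_spokes(result: DistanceResult) -> pd.DataFrame:
    """One edge per source cell: source/target positions, distance, source type."""
    cells = result.cells
    pos = {cid: cells.positions[i] for i, cid in enumerate(cells.ids)}
    rows = []
    axes = "xyz"[: cells.ndim]
    for rec in result.records.itertuples(index=False):
        sp, tp = pos[rec.source_id], pos[rec.target_id]
        row = {"source_id": rec.source_id, "source_type": rec.source_type, "target_id": rec.target_id}
        for a, v in zip(axes, sp):
            row[f"source_{a}"] = v
        for a, v in zip(axes, tp):
            row[f"target_{a}"] = v
        row["distance"] = rec.distance
        rows.append(row)
    return pd.DataFrame(rows)
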