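"""Cell-type populations: eligibility, aggregation and prediction.

A *cell-type population* is a listing of unique cell types, the number of
cells per cell type and (optionally) mean biomarker-expression values per
cell type. Populations attach to experimental datasets, to extraction
sites and — after aggregation — to 3D anatomical structures.

Datasets enter the atlas only if they (1) are spatially registered (have
an extraction site), (2) carry cell-type population data and (3) come from
a quality-controlled portal or a peer-reviewed paper. Eligible datasets
are apportioned to the anatomical structures their extraction site
collides with, proportional to normalized mesh-intersection fractions.
The aggregated per-structure populations support two predictions:

* population prediction — the expected cell-type mixture of a newly
  registered tissue block (volume-weighted mixture over collided
  structures);
* spatial-origin prediction — ranking anatomical structures by cosine
  similarity between their population vector and a query population.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    NoDataError,
    NoReferenceError,
    RecordValidationError,
    UndefinedSimilarityError,
)
from .registration import ExtractionSite, ReferenceOrganScene

__all__ = [
    "CellTypePopulation",
    "DatasetRecord",
    "OriginPrediction",
    "aggregate_as_populations",
    "align_populations",
    "cosine_similarity",
    "filter_eligible",
    "population_similarity",
    "predict_origin",
    "predict_site_population",
    "read_population_csv",
    "write_population_csv",
]


@dataclass
class CellTypePopulation:
    """Counts (and optional mean expressions) per cell type.

    ``counts`` maps cell-type ids to non-negative counts; ``biomarkers``
    names the expression panel and ``mean_expression`` maps each cell type
    to its mean-expression vector over that panel.
    """

    counts: dict[str, float]
    biomarkers: tuple[str, ...] | None = None
    mean_expression: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for ct, c in self.counts.items():
            if c < 0:
                raise RecordValidationError(f"negative count {c} for cell type {ct!r}")
        if self.counts and self.total() <= 0:
            raise RecordValidationError("non-empty population must have positive total count")
        if self.mean_expression is not None:
            if self.biomarkers is None:
                raise RecordValidationError("mean_expression requires a biomarker panel")
            k = len(self.biomarkers)
            self.mean_expression = {
                ct: np.asarray(v, dtype=float) for ct, v in self.mean_expression.items()
            }
            for ct, v in self.mean_expression.items():
                if v.shape != (k,):
                    raise RecordValidationError(
                        f"expression vector for {ct!r} has length {v.shape}, panel has {k}"
                    )

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def proportions(self) -> dict[str, float]:
        """Counts normalized to sum to 1."""
        total = self.total()
        return {ct: c / total for ct, c in self.counts.items()}

    def as_vector(self, index: list[str]) -> np.ndarray:
        """Count vector aligned on a shared cell-type index (zeros filled)."""
        return np.array([self.counts.get(ct, 0.0) for ct in index], dtype=float)


@dataclass
class DatasetRecord:
    dataset_id: str
    modality: str  # "sc_transcriptomics" | "spatial_proteomics"
    extraction_site: ExtractionSite | None = None
    population: CellTypePopulation | None = None
    provenance: str = "none"  # "portal_qc" | "peer_reviewed" | "none"

    def __post_init__(self):
        if self.modality not in ("sc_transcriptomics", "spatial_proteomics"):
            raise RecordValidationError(f"unknown modality {self.modality!r}")
        if self.provenance not in ("portal_qc", "peer_reviewed", "none"):
            raise RecordValidationError(f"unknown provenance {self.provenance!r}")


@dataclass
class OriginPrediction:
    """Ranked anatomical structures with cosine similarities in [0, 1]."""

    ranked: list[tuple[str, float]]
    query: str = ""

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.ranked[:k]


def filter_eligible(
    records: list[DatasetRecord],
) -> tuple[list[DatasetRecord], dict[str, str]]:
    """Apply the three atlas-eligibility criteria.

    A dataset is eligible iff it has an extraction site, has population
    data, and its provenance is a QC'd portal or a peer-reviewed paper.
    Returns the eligible records and, for each excluded one, the first
    failed criterion.
    """
    eligible, reasons = [], {}
    for rec in records:
        if rec.extraction_site is None:
            reasons[rec.dataset_id] = "not spatially registered (no extraction site)"
        elif rec.population is None:
            reasons[rec.dataset_id] = "no cell type population data"
        elif rec.provenance not in ("portal_qc", "peer_reviewed"):
            reasons[rec.dataset_id] = "no QC'd-portal or peer-reviewed provenance"
        else:
            eligible.append(rec)
    return eligible, reasons


def _mesh_fractions(site: ExtractionSite) -> dict[str, float]:
    """Normalized mesh-collision fractions of a site (sum to 1)."""
    recs = [a for a in site.annotations if a.method == "mesh" and a.fraction_of_block]
    total = sum(a.fraction_of_block for a in recs)
    if total <= 0:
        return {}
    return {a.as_id: a.fraction_of_block / total for a in recs}


def aggregate_as_populations(
    eligible: list[DatasetRecord],
    scene: ReferenceOrganScene | None = None,
    modality: str | None = None,
) -> dict[str, CellTypePopulation]:
    """Roll dataset populations up to anatomical-structure populations.

    Each dataset's cell counts are apportioned to the structures its site
    collides with (mesh method), proportional to normalized intersection
    fractions; per-structure counts are summed across datasets and mean
    expressions combined as count-weighted means. Transcriptomics and
    proteomics should be aggregated separately — pass ``modality`` to
    restrict. Datasets whose site has no mesh collisions are skipped with
    a warning.
    """
    known_as = {s.as_id for s in scene.structures} if scene is not None else None
    counts: dict[str, dict[str, float]] = {}
    expr_wsum: dict[str, dict[str, np.ndarray]] = {}
    expr_wtot: dict[str, dict[str, float]] = {}
    panels: dict[str, tuple[str, ...]] = {}

    for rec in eligible:
        if modality is not None and rec.modality != modality:
            continue
        fracs = _mesh_fractions(rec.extraction_site)
        if known_as is not None:
            fracs = {a: f for a, f in fracs.items() if a in known_as}
            s = sum(fracs.values())
            fracs = {a: f / s for a, f in fracs.items()} if s > 0 else {}
        if not fracs:
            warnings.warn(
                f"dataset {rec.dataset_id!r}: extraction site has no mesh-method "
                "collision records; skipped in aggregation",
                stacklevel=2,
            )
            continue
        pop = rec.population
        for as_id, w in fracs.items():
            bucket = counts.setdefault(as_id, {})
            for ct, c in pop.counts.items():
                bucket[ct] = bucket.get(ct, 0.0) + w * c
            if pop.mean_expression is not None:
                panels.setdefault(as_id, pop.biomarkers)
                if panels[as_id] != pop.biomarkers:
                    raise RecordValidationError(
                        f"dataset {rec.dataset_id!r}: biomarker panel differs from "
                        f"earlier datasets contributing to {as_id!r}"
                    )
                ws = expr_wsum.setdefault(as_id, {})
                wt = expr_wtot.setdefault(as_id, {})
                for ct, vec in pop.mean_expression.items():
                    weight = w * pop.counts.get(ct, 0.0)
                    if weight <= 0:
                        continue
                    ws[ct] = ws.get(ct, 0.0) + weight * vec
                    wt[ct] = wt.get(ct, 0.0) + weight

    out: dict[str, CellTypePopulation] = {}
    for as_id, ct_counts in counts.items():
        mean_expr = None
        panel = panels.get(as_id)
        if as_id in expr_wsum:
            mean_expr = {
                ct: expr_wsum[as_id][ct] / expr_wtot[as_id][ct] for ct in expr_wsum[as_id]
            }
        out[as_id] = CellTypePopulation(
            counts=ct_counts, biomarkers=panel, mean_expression=mean_expr
        )
    return out


def predict_site_population(
    site: ExtractionSite,
    as_pops: dict[str, CellTypePopulation],
    total_cells: float = 1.0,
) -> CellTypePopulation:
    """Predict the cell-type population of a registered tissue block.

    The prediction is the mixture of the collided structures' proportion
    vectors, weighted by normalized mesh-intersection fractions, scaled by
    ``total_cells`` (1.0 reports proportions). Structures absent from
    ``as_pops`` trigger a partial-coverage warning and the weights are
    renormalized over the known ones.
    """
    fracs = _mesh_fractions(site)
    if not fracs:
        raise NoDataError(f"site {site.site_id!r} has no mesh-method collision records")
    known = {a: w for a, w in fracs.items() if a in as_pops}
    if not known:
        raise NoDataError(
            f"site {site.site_id!r}: none of its colliding structures have population data"
        )
    if len(known) < len(fracs):
        missing = sorted(set(fracs) - set(known))
        warnings.warn(
            f"site {site.site_id!r}: no population data for {missing}; "
            "weights renormalized over covered structures",
            stacklevel=2,
        )
    wsum = sum(known.values())
    mixture: dict[str, float] = {}
    for as_id, w in known.items():
        for ct, p in as_pops[as_id].proportions().items():
            mixture[ct] = mixture.get(ct, 0.0) + (w / wsum) * p
    return CellTypePopulation(counts={ct: p * total_cells for ct, p in mixture.items()})


def cosine_similarity(u, v) -> float:
    """Cosine of the angle between two non-negative vectors.

    1 means identical direction, 0 means no shared support. The inputs
    must be aligned on a shared cell-type index (see
    :func:`align_populations`).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vectors must be aligned; shapes {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError("cosine similarity is undefined for a zero vector")
    sim = float(np.dot(u, v) / (nu * nv))
    return float(min(max(sim, -1.0), 1.0))


def align_populations(
    a: CellTypePopulation, b: CellTypePopulation
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align two populations on the union of their cell-type supports."""
    index = sorted(set(a.counts) | set(b.counts))
    return a.as_vector(index), b.as_vector(index), index


def population_similarity(a: CellTypePopulation, b: CellTypePopulation) -> float:
    """Cosine similarity between two populations on their union support."""
    u, v, _ = align_populations(a, b)
    return cosine_similarity(u, v)


def predict_origin(
    query: CellTypePopulation,
    as_pops: dict[str, CellTypePopulation],
    top_k: int | None = None,
    query_description: str = "",
) -> OriginPrediction:
    """Rank anatomical structures as the likely spatial origin of a query.

    Structures are ordered by cosine similarity between their proportion
    vector and the query's, ties broken lexicographically by as_id.
    Proportions are used, so the ranking is invariant to sequencing depth.
    """
    if not as_pops:
        raise NoReferenceError("no reference anatomical-structure populations")
    if not query.counts:
        raise NoDataError("query population is empty")
    scored = [
        (as_id, population_similarity(query, pop)) for as_id, pop in sorted(as_pops.items())
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    if top_k is not None:
        scored = scored[: int(top_k)]
    return OriginPrediction(ranked=scored, query=query_description)


# ---------------------------------------------------------------------------
# CSV I/O: columns id, cell_type_id, count[, one column per biomarker mean]

def read_population_csv(source) -> dict[str, CellTypePopulation]:
    """Read populations keyed by the ``id`` column (dataset or structure id)."""
    if isinstance(source, pd.DataFrame):
        df = source
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        df = pd.read_csv(source)
    else:
        df = pd.read_csv(io.StringIO(str(source)))
    required = {"id", "cell_type_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise RecordValidationError(f"population CSV missing columns: {sorted(missing)}")
    biomarker_cols = [c for c in df.columns if c not in required]
    out: dict[str, CellTypePopulation] = {}
    for pid, grp in df.groupby("id", sort=False):
        if grp["cell_type_id"].duplicated().any():
            raise DuplicateIdError(f"population {pid!r} lists a cell type twice")
        counts = dict(zip(grp["cell_type_id"], grp["count"].astype(float)))
        mean_expr = None
        panel = None
        if biomarker_cols and not grp[biomarker_cols].isna().all().all():
            panel = tuple(biomarker_cols)
            mean_expr = {
                ct: row.to_numpy(dtype=float)
                for ct, (_, row) in zip(grp["cell_type_id"], grp[biomarker_cols].iterrows())
            }
        out[str(pid)] = CellTypePopulation(counts=counts, biomarkers=panel, mean_expression=mean_expr)
    return out


def write_population_csv(pops: dict[str, CellTypePopulation], path: str | Path | None = None) -> str:
    """Serialize populations to CSV (inverse of :func:`read_population_csv`)."""
    panel: tuple[str, ...] | None = None
    for pop in pops.values():
        if pop.biomarkers is not None:
            if panel is not None and panel != pop.biomarkers:
                raise RecordValidationError("all populations in one CSV must share a biomarker panel")
            panel = pop.biomarkers
    rows = []
    for pid in sorted(pops):
        pop = pops[pid]
        for ct in sorted(pop.counts):
            row = {"id": pid, "cell_type_id": ct, "count": pop.counts[ct]}
            if panel is not None:
                vec = (pop.mean_expression or {}).get(ct)
                for i, bm in enumerate(panel):
                    row[bm] = float(vec[i]) if vec is not None else np.nan
            rows.append(row)
    columns = ["id", "cell_type_id", "count"] + (list(panel) if panel else [])
    text = pd.DataFrame(rows, columns=columns).to_csv(index=False)
    if path is not None:
        Path(path).write_text(text)
    return text
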