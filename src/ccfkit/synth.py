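"""Deterministic synthetic fixtures: toy organ scenes, extraction sites,
structure populations and layered cell tables.

These generators stand in for the real atlas inputs (reference-organ
meshes, RUI registrations, annotated datasets, multiplexed-imaging cell
tables) so that every computation in the toolkit can be exercised without
downloads. They are pure functions of (spec, seed): nested box/ellipsoid
"organs" with a matching partonomy table, tissue blocks sampled inside
known structures, Dirichlet-distinct cell-type signatures per structure
with multinomially sampled datasets, and banded tissues with sprinkled
vascular cells emulating the layered architecture of real FTU-bearing
tissue (e.g. intestinal crypts).
"""

from __future__ import annotations

import uuid as _uuid
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .asctb import AsctbTable, parse_asctb_table
from .distances import CellTable
from .errors import ContainmentError, RecordValidationError, SizingError
from .geometry import Placement, TriangleMesh
from .populations import CellTypePopulation, DatasetRecord
from .registration import (
    ExtractionSite,
    ReferenceOrganScene,
    SceneStructure,
    annotate_site,
)

__all__ = [
    "SceneSpec",
    "StructureSpec",
    "Band",
    "TissueSimSpec",
    "make_scene",
    "sample_extraction_sites",
    "simulate_as_populations",
    "simulate_dataset_from_site",
    "simulate_layered_cells",
]


def _subseed(seed: int, *salt) -> int:
    """Deterministic sub-seed below 2**31 derived from a root seed.

    Uses crc32 for the salt so the derivation is stable across processes
    (unlike built-in ``hash`` for strings).
    """
    salt_ints = [zlib.crc32(str(s).encode()) & 0x7FFFFFFF for s in salt]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *salt_ints])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class StructureSpec:
    as_id: str
    label: str
    shape: str  # "box" | "ellipsoid"
    center: tuple[float, float, float]
    half_sizes: tuple[float, float, float]
    parent: str | None = None

    def __post_init__(self):
        if self.shape not in ("box", "ellipsoid"):
            raise RecordValidationError(f"shape must be 'box' or 'ellipsoid', got {self.shape!r}")


@dataclass
class SceneSpec:
    """A toy reference organ: an overall extent and nested structures."""

    organ_id: str
    extent: tuple[float, float, float]
    structures: list[StructureSpec]
    sex: str = "unknown"
    organ_label: str = "toy organ"

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            organ_id=d["organ_id"],
            extent=tuple(d["extent"]),
            structures=[
                StructureSpec(
                    as_id=s["as_id"],
                    label=s.get("label", s["as_id"]),
                    shape=s.get("shape", "box"),
                    center=tuple(s["center"]),
                    half_sizes=tuple(s["half_sizes"]),
                    parent=s.get("parent"),
                )
                for s in d["structures"]
            ],
            sex=d.get("sex", "unknown"),
            organ_label=d.get("organ_label", "toy organ"),
        )

    @classmethod
    def from_yaml(cls, source) -> "SceneSpec":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text))


def _box_mesh(center, half_sizes) -> TriangleMesh:
    placement = Placement(
        dimensions=tuple(2 * h for h in half_sizes),
        translation=tuple(c - h for c, h in zip(center, half_sizes)),
    )
    from .geometry import place_cuboid

    return place_cuboid(placement)


def _ellipsoid_mesh(center, half_sizes, subdivisions: int = 4) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = ico.vertices * np.asarray(half_sizes, dtype=float) + np.asarray(center, dtype=float)
    return TriangleMesh(verts, ico.faces.copy())


def make_scene(spec: SceneSpec, subdivisions: int = 4) -> tuple[ReferenceOrganScene, AsctbTable]:
    """Build a reference-organ scene and its matching partonomy table.

    Children must fit geometrically inside their parent's extent (checked
    at AABB level). The returned ASCT+B table has one row per structure
    whose AS path mirrors the parent hierarchy, rooted at the organ.
    """
    by_id = {s.as_id: s for s in spec.structures}
    if len(by_id) != len(spec.structures):
        raise RecordValidationError("structure as_ids must be unique")

    structures = []
    meshes: dict[str, TriangleMesh] = {}
    for s in spec.structures:
        mesh = (
            _box_mesh(s.center, s.half_sizes)
            if s.shape == "box"
            else _ellipsoid_mesh(s.center, s.half_sizes, subdivisions)
        )
        meshes[s.as_id] = mesh
        structures.append(SceneStructure(as_id=s.as_id, label=s.label, mesh=mesh))

    organ_lo = np.zeros(3)
    organ_hi = np.asarray(spec.extent, dtype=float)
    for s in spec.structures:
        box = meshes[s.as_id].aabb
        if s.parent is None:
            lo, hi = organ_lo, organ_hi
            pname = spec.organ_label
        else:
            if s.parent not in meshes:
                raise RecordValidationError(f"structure {s.as_id!r} names unknown parent {s.parent!r}")
            pbox = meshes[s.parent].aabb
            lo, hi = pbox.min_corner, pbox.max_corner
            pname = s.parent
        if np.any(box.min_corner < lo - 1e-9) or np.any(box.max_corner > hi + 1e-9):
            raise ContainmentError(f"structure {s.as_id!r} escapes the extent of {pname!r}")

    def path(s: StructureSpec) -> list[StructureSpec]:
        chain, cur = [s], s
        while cur.parent is not None:
            cur = by_id[cur.parent]
            chain.append(cur)
        return chain[::-1]

    depth = max(len(path(s)) for s in spec.structures) + 1  # + organ root
    columns = []
    for i in range(1, depth + 1):
        columns += [f"AS/{i}", f"AS/{i}/ID"]
    columns += ["CT/1", "CT/1/ID"]
    records = []
    for s in spec.structures:
        rec = dict.fromkeys(columns, "")
        rec["AS/1"], rec["AS/1/ID"] = spec.organ_label, spec.organ_id
        for i, node in enumerate(path(s), start=2):
            rec[f"AS/{i}"], rec[f"AS/{i}/ID"] = node.label, node.as_id
        records.append(rec)
    table = parse_asctb_table(pd.DataFrame.from_records(records, columns=columns))

    scene = ReferenceOrganScene(organ_id=spec.organ_id, sex=spec.sex, structures=structures)
    return scene, table


def _deterministic_uuid(rng: np.random.Generator) -> str:
    return str(_uuid.UUID(bytes=rng.bytes(16), version=4))


def sample_extraction_sites(
    scene: ReferenceOrganScene,
    per_structure: int = 1,
    jitter: float = 0.0,
    block_scale: float = 0.3,
    seed: int = 0,
    annotate: bool = True,
    resolution: int = 64,
) -> tuple[list[ExtractionSite], dict[str, str]]:
    """Sample tissue blocks centered inside each scene structure.

    Block edge lengths are ``block_scale`` times the structure's AABB
    extent; centers are offset by ``jitter`` (fraction of the structure's
    half-extent, uniform per axis). Returns the sites and a map
    site_id -> ground-truth structure id. With ``annotate=True`` each site
    carries mesh-method collision records against the scene.
    """
    if not (0 < block_scale):
        raise SizingError("block_scale must be positive")
    rng = np.random.default_rng(_subseed(seed, "sites"))
    sites: list[ExtractionSite] = []
    truth: dict[str, str] = {}
    for structure in scene.structures:
        box = structure.mesh.aabb
        dims = block_scale * box.extent
        if np.any(dims >= box.extent):
            raise SizingError(
                f"block dims {tuple(dims)} do not fit inside structure {structure.as_id!r}"
            )
        for _ in range(per_structure):
            offset = jitter * (box.extent / 2) * rng.uniform(-1, 1, size=3)
            center = (box.min_corner + box.max_corner) / 2 + offset
            translation = center - dims / 2
            site = ExtractionSite(
                site_id=_deterministic_uuid(rng),
                placement=Placement(dimensions=tuple(dims), translation=tuple(translation)),
                reference_organ=scene.organ_id,
                operator="ccfkit synthetic sampler",
                date="2024-01-01",
            )
            if annotate:
                site.annotations = annotate_site(
                    site, scene, method="mesh", resolution_or_samples=resolution, seed=seed
                )
            sites.append(site)
            truth[site.site_id] = structure.as_id
    return sites, truth


def simulate_as_populations(
    scene: ReferenceOrganScene,
    n_types: int | None = None,
    peak_concentration: float = 50.0,
    background_concentration: float = 0.2,
    types_per_structure: int = 2,
    total_cells: float = 10_000.0,
    seed: int = 0,
) -> dict[str, CellTypePopulation]:
    """Draw a Dirichlet-distinct cell-type signature for every structure.

    Each structure's concentration vector peaks on its own disjoint block
    of ``types_per_structure`` cell types (guaranteeing distinct modes)
    with a small shared background, so signatures are well separated in
    cosine space. A background of exactly 0 yields strictly disjoint
    (orthogonal) signatures. Counts are the drawn proportions scaled by
    ``total_cells``.
    """
    n_structures = len(scene.structures)
    if n_types is None:
        n_types = n_structures * types_per_structure
    if n_types < n_structures:
        raise RecordValidationError("need at least one cell type per structure")
    if peak_concentration <= 0 or background_concentration < 0:
        raise RecordValidationError(
            "peak concentration must be positive and background non-negative"
        )
    cell_types = [f"CL:{9000000 + i}" for i in range(n_types)]
    out: dict[str, CellTypePopulation] = {}
    for i, structure in enumerate(sorted(scene.structures, key=lambda s: s.as_id)):
        rng = np.random.default_rng(_subseed(seed, "signature", structure.as_id))
        conc = np.full(n_types, float(background_concentration))
        lo = (i * types_per_structure) % n_types
        for j in range(types_per_structure):
            conc[(lo + j) % n_types] = peak_concentration
        props = np.zeros(n_types)
        positive = conc > 0
        props[positive] = rng.dirichlet(conc[positive])
        out[structure.as_id] = CellTypePopulation(
            counts={ct: float(p * total_cells) for ct, p in zip(cell_types, props) if p > 0}
        )
    return out


def simulate_dataset_from_site(
    site: ExtractionSite,
    populations: dict[str, CellTypePopulation],
    n_cells: int = 1000,
    noise: float = 0.0,
    seed: int = 0,
    modality: str = "sc_transcriptomics",
    provenance: str = "portal_qc",
) -> DatasetRecord:
    """Sample a dataset's cell-type counts from a site's volume-weighted mixture.

    The expected mixture is the normalized-intersection-fraction-weighted
    combination of the collided structures' proportion vectors; ``noise``
    applies multiplicative lognormal(0, noise) perturbation per cell type
    before renormalizing; counts are then multinomial(n_cells, mixture).
    """
    from .populations import predict_site_population

    expected = predict_site_population(site, populations)
    index = sorted(expected.counts)
    p = np.array([expected.counts[ct] for ct in index])
    p = p / p.sum()
    rng = np.random.default_rng(_subseed(seed, "dataset", site.site_id))
    if noise > 0:
        p = p * rng.lognormal(mean=0.0, sigma=noise, size=len(p))
        p = p / p.sum()
    counts = rng.multinomial(int(n_cells), p)
    return DatasetRecord(
        dataset_id=f"ds-{site.site_id}",
        modality=modality,
        extraction_site=site,
        population=CellTypePopulation(
            counts={ct: float(c) for ct, c in zip(index, counts) if c > 0}
        ),
        provenance=provenance,
    )


@dataclass(frozen=True)
class Band:
    mixture: dict[str, float]
    y_range: tuple[float, float]

    def __post_init__(self):
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise RecordValidationError(f"band mixture must sum to 1, got {total}")
        if self.y_range[1] <= self.y_range[0]:
            raise RecordValidationError("band y_range must be increasing")


@dataclass
class TissueSimSpec:
    """A layered 2D tissue: stacked bands with distinct type mixtures plus
    uniformly sprinkled vascular cells."""

    bands: list[Band]
    x_extent: tuple[float, float] = (0.0, 1000.0)
    vascular_label: str = "Endothelial"
    vascular_density: float = 0.05
    n_cells: int = 3000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.vascular_density <= 1.0):
            raise RecordValidationError("vascular density must be in [0, 1]")
        if self.n_cells < 1:
            raise RecordValidationError("n_cells must be positive")


def simulate_layered_cells(spec: TissueSimSpec) -> CellTable:
    """Place cells uniformly within bands, draw types from band mixtures and
    sprinkle vascular cells uniformly over the whole tissue.

    Of the ``n_cells`` total, ``round(vascular_density * n_cells)`` are
    vascular; the remainder are split across bands proportional to band
    area. Positions are µm.
    """
    rng = np.random.default_rng(_subseed(spec.seed, "layers"))
    n_vasc = int(round(spec.vascular_density * spec.n_cells))
    n_tissue = spec.n_cells - n_vasc
    width = spec.x_extent[1] - spec.x_extent[0]
    areas = np.array([(b.y_range[1] - b.y_range[0]) * width for b in spec.bands], dtype=float)
    n_per_band = rng.multinomial(n_tissue, areas / areas.sum())

    xs, ys, types = [], [], []
    for band, nb in zip(spec.bands, n_per_band):
        xs.append(rng.uniform(spec.x_extent[0], spec.x_extent[1], size=nb))
        ys.append(rng.uniform(band.y_range[0], band.y_range[1], size=nb))
        labels = sorted(band.mixture)
        probs = np.array([band.mixture[l] for l in labels])
        types.append(np.array(labels, dtype=object)[rng.choice(len(labels), size=nb, p=probs)])
    y_lo = min(b.y_range[0] for b in spec.bands)
    y_hi = max(b.y_range[1] for b in spec.bands)
    xs.append(rng.uniform(spec.x_extent[0], spec.x_extent[1], size=n_vasc))
    ys.append(rng.uniform(y_lo, y_hi, size=n_vasc))
    types.append(np.full(n_vasc, spec.vascular_label, dtype=object))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.concatenate(types).astype(str)
    ids = np.array([f"c{i:06d}" for i in range(len(x))])
    return CellTable(ids=ids, positions=np.column_stack([x, y]), types=t)


def band_truth(spec: TissueSimSpec, cells: CellTable) -> np.ndarray:
    """Ground-truth band index per cell (vascular cells get the band they sit in)."""
    idx = np.full(len(cells), -1, dtype=int)
    y = cells.positions[:, 1]
    for i, band in enumerate(spec.bands):
        mask = (y >= band.y_range[0]) & (y <= band.y_range[1]) & (idx < 0)
        idx[mask] = i
    return idx
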