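"""Extraction-site records, reference-organ scenes and collision annotation.

An *extraction site* is the digital cuboid recording where a tissue block
was taken: its 3D size, rotation and position relative to a reference
organ, plus provenance (operator, date) and, once annotated, the list of
anatomical structures the cuboid collides with. The JSON dialect used here
is a minimal, documented one: one object per site with explicit
``dimensions_mm`` / ``rotation_degrees`` / ``translation_mm`` triples.
Registration sets group sites by study and carry a name plus link strings
(typically DOIs).
"""

from __future__ import annotations

import json
import uuid as _uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .errors import (
    DuplicateIdError,
    RecordValidationError,
    ReferenceMismatchError,
    SchemaError,
)
from .geometry import (
    Placement,
    TriangleMesh,
    aabb_collides,
    intersection_volume,
    mesh_volume,
    place_cuboid,
)
from .meshio import read_mesh, write_mesh

__all__ = [
    "CollisionRecord",
    "ExtractionSite",
    "ReferenceOrganScene",
    "SceneStructure",
    "annotate_site",
    "load_scene",
    "read_extraction_sites",
    "save_scene",
    "write_extraction_sites",
    "write_registration_set",
]


@dataclass(frozen=True)
class CollisionRecord:
    """One anatomical structure a placed tissue block intersects.

    ``bbox`` records are approximate (no volume); ``mesh`` records carry the
    intersection volume in mm^3 and the fraction of the block it represents.
    """

    as_id: str
    method: Literal["bbox", "mesh"]
    intersection_volume: float | None = None
    fraction_of_block: float | None = None

    def __post_init__(self):
        if self.method not in ("bbox", "mesh"):
            raise RecordValidationError(f"collision method must be 'bbox' or 'mesh', got {self.method!r}")
        if self.method == "mesh":
            if self.intersection_volume is None or self.fraction_of_block is None:
                raise RecordValidationError("mesh collision records require volume and fraction")
            if not (0.0 <= self.fraction_of_block <= 1.0 + 1e-9):
                raise RecordValidationError(f"fraction_of_block {self.fraction_of_block} outside [0, 1]")


@dataclass
class ExtractionSite:
    site_id: str
    placement: Placement
    reference_organ: str
    operator: str = ""
    date: str = ""
    sections: dict | None = None  # {"count": int, "thickness_um": float}; inherits placement
    annotations: list[CollisionRecord] = field(default_factory=list)

    def __post_init__(self):
        try:
            _uuid.UUID(self.site_id)
        except (ValueError, AttributeError, TypeError) as exc:
            raise RecordValidationError(f"site id {self.site_id!r} is not a valid UUID") from exc


@dataclass(frozen=True)
class SceneStructure:
    as_id: str
    label: str
    mesh: TriangleMesh


@dataclass
class ReferenceOrganScene:
    """A reference organ: an id, a donor sex and its anatomical-structure meshes."""

    organ_id: str
    sex: Literal["male", "female", "unknown"]
    structures: list[SceneStructure]

    def __post_init__(self):
        if self.sex not in ("male", "female", "unknown"):
            raise RecordValidationError(f"sex must be male/female/unknown, got {self.sex!r}")
        ids = [s.as_id for s in self.structures]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("anatomical-structure ids must be unique within a scene")

    def structure(self, as_id: str) -> SceneStructure:
        for s in self.structures:
            if s.as_id == as_id:
                return s
        raise KeyError(as_id)


_REQUIRED_SITE_KEYS = (
    "id",
    "dimensions_mm",
    "rotation_degrees",
    "translation_mm",
    "reference_organ",
    "operator",
    "date",
)


def _site_from_dict(entry: dict) -> ExtractionSite:
    for key in _REQUIRED_SITE_KEYS:
        if key not in entry:
            raise SchemaError(key, context=f"site {entry.get('id', '<unknown>')!r}")
    placement = Placement(
        dimensions=tuple(entry["dimensions_mm"]),
        rotation=tuple(entry["rotation_degrees"]),
        translation=tuple(entry["translation_mm"]),
    )
    annotations = [
        CollisionRecord(
            as_id=a["as_id"],
            method=a["method"],
            intersection_volume=a.get("intersection_volume_mm3"),
            fraction_of_block=a.get("fraction_of_block"),
        )
        for a in entry.get("annotations", [])
    ]
    return ExtractionSite(
        site_id=entry["id"],
        placement=placement,
        reference_organ=entry["reference_organ"],
        operator=entry["operator"],
        date=entry["date"],
        sections=entry.get("sections"),
        annotations=annotations,
    )


def _site_to_dict(site: ExtractionSite) -> dict:
    entry = {
        "id": site.site_id,
        "reference_organ": site.reference_organ,
        "operator": site.operator,
        "date": site.date,
        "dimensions_mm": list(site.placement.dimensions),
        "rotation_degrees": list(site.placement.rotation),
        "translation_mm": list(site.placement.translation),
        "annotations": [
            {
                "as_id": a.as_id,
                "method": a.method,
                **(
                    {
                        "intersection_volume_mm3": a.intersection_volume,
                        "fraction_of_block": a.fraction_of_block,
                    }
                    if a.method == "mesh"
                    else {}
                ),
            }
            for a in site.annotations
        ],
    }
    if site.sections is not None:
        entry["sections"] = site.sections
    return entry


def read_extraction_sites(source) -> list[ExtractionSite]:
    """Read extraction sites from a JSON document.

    ``source`` may be a dict, a JSON string, or a path to a JSON file.
    Accepts both a bare list of sites and a registration-set document with a
    top-level ``sites`` key. Round-trips losslessly through
    :func:`write_extraction_sites`.
    """
    if isinstance(source, Path):
        doc = json.loads(source.read_text())
    elif isinstance(source, str):
        stripped = source.lstrip()
        if stripped.startswith(("{", "[")):
            doc = json.loads(source)
        else:
            doc = json.loads(Path(source).read_text())
    else:
        doc = source
    if isinstance(doc, dict):
        if "sites" not in doc:
            raise SchemaError("sites", context="registration document")
        entries = doc["sites"]
    else:
        entries = doc
    return [_site_from_dict(e) for e in entries]


def write_extraction_sites(sites: list[ExtractionSite]) -> dict:
    """Serialize sites to the JSON dialect read by :func:`read_extraction_sites`."""
    return {"sites": [_site_to_dict(s) for s in sites]}


def write_registration_set(
    sites: list[ExtractionSite],
    metadata: dict,
    path: str | Path | None = None,
) -> dict:
    """Build a registration-set document grouping sites by study.

    ``metadata`` carries at least a ``name``; ``links`` (e.g. DOI strings)
    are passed through. Serialization uses sorted keys so that
    write -> read -> write is byte-stable.
    """
    if not sites:
        raise RecordValidationError("a registration set needs at least one site")
    ids = [s.site_id for s in sites]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DuplicateIdError(f"duplicate site ids in registration set: {sorted(dupes)}")
    doc = {
        "registration_set": {
            "name": metadata.get("name", ""),
            "links": list(metadata.get("links", [])),
        },
        "sites": [_site_to_dict(s) for s in sites],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def registration_json(doc: dict) -> str:
    """Canonical (sorted-key) JSON text for a registration document."""
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def annotate_site(
    site: ExtractionSite,
    scene: ReferenceOrganScene,
    method: Literal["bbox", "mesh"] = "mesh",
    collision_method: str = "auto",
    resolution_or_samples: int | None = None,
    seed: int = 0,
) -> list[CollisionRecord]:
    """Compute the collision records of a site against a reference-organ scene.

    ``bbox`` reports every structure whose AABB overlaps the placed block's
    AABB (approximate but fast; sorted by as_id, no volumes). ``mesh``
    computes intersection volumes and keeps only structures with positive
    overlap, sorted by descending fraction of the block's volume.
    """
    if site.reference_organ != scene.organ_id:
        raise ReferenceMismatchError(
            f"site references organ {site.reference_organ!r} but scene is {scene.organ_id!r}"
        )
    block = place_cuboid(site.placement)
    if method == "bbox":
        records = [
            CollisionRecord(as_id=s.as_id, method="bbox")
            for s in scene.structures
            if aabb_collides(block.aabb, s.mesh.aabb)
        ]
        return sorted(records, key=lambda r: r.as_id)
    if method != "mesh":
        raise ValueError(f"unknown annotation method {method!r}")
    block_vol = mesh_volume(block)
    records = []
    for s in scene.structures:
        vol = intersection_volume(
            block, s.mesh, method=collision_method,
            resolution_or_samples=resolution_or_samples, seed=seed,
        )
        if vol > 0:
            records.append(
                CollisionRecord(
                    as_id=s.as_id,
                    method="mesh",
                    intersection_volume=vol,
                    fraction_of_block=min(vol / block_vol, 1.0),
                )
            )
    return sorted(records, key=lambda r: (-r.fraction_of_block, r.as_id))


def save_scene(scene: ReferenceOrganScene, directory: str | Path) -> Path:
    """Write a scene as a manifest JSON plus one OFF file per structure."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"organ_id": scene.organ_id, "sex": scene.sex, "structures": []}
    for s in scene.structures:
        fname = s.as_id.replace(":", "_") + ".off"
        write_mesh(s.mesh, directory / fname)
        manifest["structures"].append({"as_id": s.as_id, "label": s.label, "mesh": fname})
    (directory / "scene.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return directory / "scene.json"


def load_scene(directory: str | Path) -> ReferenceOrganScene:
    """Load a scene written by :func:`save_scene`."""
    directory = Path(directory)
    manifest = json.loads((directory / "scene.json").read_text())
    for key in ("organ_id", "sex", "structures"):
        if key not in manifest:
            raise SchemaError(key, context="scene manifest")
    structures = [
        SceneStructure(s["as_id"], s.get("label", s["as_id"]), read_mesh(directory / s["mesh"]))
        for s in manifest["structures"]
    ]
    return ReferenceOrganScene(manifest["organ_id"], manifest["sex"], structures)
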