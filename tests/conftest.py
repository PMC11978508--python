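import numpy as np
import pytest

from ccfkit.geometry import Placement, place_cuboid
from ccfkit.registration import ExtractionSite, ReferenceOrganScene, SceneStructure
from ccfkit.synth import Band, SceneSpec, StructureSpec, TissueSimSpec, make_scene


@pytest.fixture
def unit_cube():
    return place_cuboid(Placement((1.0, 1.0, 1.0)))


@pytest.fixture
def two_box_scene():
    """Two disjoint equal boxes, side 2, centered at (2,2,2) and (7,2,2)."""
    a = place_cuboid(Placement((2, 2, 2), translation=(1, 1, 1)))
    b = place_cuboid(Placement((2, 2, 2), translation=(6, 1, 1)))
    return ReferenceOrganScene(
        organ_id="UBERON:0000948",
        sex="female",
        structures=[
            SceneStructure("UBERON:0000001", "structure A", a),
            SceneStructure("UBERON:0000002", "structure B", b),
        ],
    )


@pytest.fixture
def four_structure_spec():
    """Four well-separated box structures in a 10 mm toy organ."""
    return SceneSpec(
        organ_id="UBERON:0000948",
        extent=(10.0, 10.0, 10.0),
        structures=[
            StructureSpec("UBERON:0000001", "A", "box", (2, 2, 2), (1.5, 1.5, 1.5)),
            StructureSpec("UBERON:0000002", "B", "box", (7, 2, 2), (1.5, 1.5, 1.5)),
            StructureSpec("UBERON:0000003", "C", "box", (2, 7, 2), (1.5, 1.5, 1.5)),
            StructureSpec("UBERON:0000004", "D", "box", (7, 7, 7), (1.5, 1.5, 1.5)),
        ],
    )


@pytest.fixture
def four_structure_scene(four_structure_spec):
    scene, table = make_scene(four_structure_spec)
    return scene


@pytest.fixture
def three_band_spec():
    """Layered tissue with near-disjoint type mixtures per band."""
    return TissueSimSpec(
        bands=[
            Band(mixture={"TypeA": 0.6, "TypeB": 0.4}, y_range=(0.0, 300.0)),
            Band(mixture={"TypeC": 0.5, "TypeD": 0.5}, y_range=(300.0, 600.0)),
            Band(mixture={"TypeE": 0.7, "TypeF": 0.3}, y_range=(600.0, 900.0)),
        ],
        x_extent=(0.0, 900.0),
        vascular_label="Endothelial",
        vascular_density=0.05,
        n_cells=3000,
        seed=11,
    )


def make_site(dims, translation, rotation=(0, 0, 0), organ="UBERON:0000948",
              site_id="00000000-0000-4000-8000-000000000001"):
    return ExtractionSite(
        site_id=site_id,
        placement=Placement(dimensions=dims, rotation=rotation, translation=translation),
        reference_organ=organ,
        operator="tester",
        date="2024-01-01",
    )


@pytest.fixture
def site_factory():
    return make_site


def random_box_pair(rng):
    """Two overlapping axis-aligned boxes with analytic overlap volume."""
    lo_a = rng.uniform(0, 2, 3)
    ext_a = rng.uniform(0.5, 2.0, 3)
    # offset keeps a substantial overlap on every axis
    lo_b = lo_a + rng.uniform(-0.4, 0.4, 3) * ext_a
    ext_b = rng.uniform(0.5, 2.0, 3)
    a = place_cuboid(Placement(tuple(ext_a), translation=tuple(lo_a)))
    b = place_cuboid(Placement(tuple(ext_b), translation=tuple(lo_b)))
    overlap = np.prod(
        np.maximum(
            np.minimum(lo_a + ext_a, lo_b + ext_b) - np.maximum(lo_a, lo_b), 0.0
        )
    )
    return a, b, float(overlap)
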