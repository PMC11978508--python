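# ccfkit

A toolkit for the computations behind 3D tissue-atlas *common coordinate
frameworks* (CCFs): registering tissue-block cuboids against reference-organ
meshes, validating ASCT+B-style anatomy/cell-type/biomarker tables, rolling
experimental cell-type populations up to anatomical structures and predicting
from them, measuring cell-to-vasculature distances, and computing hierarchical
multiscale cell neighborhoods.

It is aimed at computational biologists building or consuming spatially
registered single-cell data: the inputs are triangle meshes (OFF/OBJ),
RUI-style extraction-site JSON, flat ASCT+B and crosswalk CSVs, population
CSVs and per-cell coordinate tables. A synthetic-fixture module generates all
of these, so the whole pipeline runs without any downloads.

## What it computes

**Spatial registration.** A tissue block is a cuboid with size
(x, y, z in mm), intrinsic X→Y→Z Euler rotation and position. Collision
against anatomical-structure meshes is tested two ways: fast axis-aligned
bounding-box overlap (approximate, a superset), and mesh-level intersection
*volumes* — analytic for axis-aligned box pairs, voxel-center counting on a
grid, or Monte-Carlo sampling. A site's mesh-level annotation lists each
structure with |block ∩ structure| in mm³ and the fraction of the block's
volume it represents.

**Population aggregation and prediction.** A *cell-type population* is a
vector of counts n_c per cell type c (plus optional mean biomarker
expressions). Datasets qualify for aggregation if they are spatially
registered, carry population data and have QC'd-portal or peer-reviewed
provenance. Each qualifying dataset's counts are apportioned to its collided
structures proportionally to normalized intersection fractions w_s and
summed, giving per-structure reference populations. Two predictions follow:

* **block population**: p̂ = Σ_s w_s · p_s, the volume-weighted mixture of
  the collided structures' proportion vectors;
* **spatial origin**: structures ranked by cosine similarity
  cos(u, v) = u·v / (‖u‖‖v‖) between the query's and each structure's
  proportion vector (1 = identical direction, 0 = no shared support).

**VCCF distances.** For each cell, the Euclidean distance to the nearest
cell of a target type set (typically endothelial), with per-type
distribution summaries and exportable "spoke" edges.

**Multiscale neighborhoods.** Each cell's k-NN window (n = 10) is summarized
as a cell-type composition vector and clustered (k-means) into
*neighborhoods*; neighborhood labels over larger windows (n = 100) give
*communities*; community labels over n = 300 windows give *tissue units*.
A multilevel graph links cell types → neighborhoods → communities → tissue
units with edge weights equal to the fraction of the lower node's cells in
the upper node.

## Worked example

```python
from ccfkit.synth import (SceneSpec, StructureSpec, make_scene,
                          sample_extraction_sites, simulate_as_populations,
                          simulate_dataset_from_site)
from ccfkit.populations import (aggregate_as_populations, filter_eligible,
                                predict_origin, predict_site_population)

spec = SceneSpec(
    organ_id="UBERON:0000948", organ_label="toy heart", extent=(10, 10, 10),
    structures=[
        StructureSpec("UBERON:0000001", "left wall", "box", (2, 2, 2), (1.5, 1.5, 1.5)),
        StructureSpec("UBERON:0000002", "right wall", "box", (7, 2, 2), (1.5, 1.5, 1.5)),
        StructureSpec("UBERON:0000003", "septum", "box", (2, 7, 2), (1.5, 1.5, 1.5)),
        StructureSpec("UBERON:0000004", "apex", "box", (7, 7, 7), (1.5, 1.5, 1.5)),
    ],
)
scene, table = make_scene(spec)
sites, truth = sample_extraction_sites(scene, per_structure=1, jitter=0.0, seed=7)
as_pops = simulate_as_populations(scene, seed=7)
datasets = [simulate_dataset_from_site(s, as_pops, n_cells=2000, seed=7 + i)
            for i, s in enumerate(sites)]
eligible, _ = filter_eligible(datasets)
agg = aggregate_as_populations(eligible, scene)

pred = predict_origin(datasets[0].population, agg, top_k=3)
for as_id, sim in pred.ranked:
    print(f"  {as_id}  cosine={sim:.4f}")
```

prints the ranked origin candidates for the first dataset (whose block sits
entirely inside the left wall):

```
  UBERON:0000001  cosine=1.0000
  UBERON:0000003  cosine=0.0073
  UBERON:0000002  cosine=0.0031
```

i.e. the true structure is recovered with near-perfect similarity and the
other structures, whose Dirichlet signatures barely share support, score near
zero. Predicting the block's population back from the aggregated atlas,

```python
p = predict_site_population(sites[0], agg, total_cells=1000)
```

yields expected counts (606.0 and 390.5 cells for the two cell types that
dominate the left wall's signature) that match the structure's aggregated
proportions exactly, because the block collides with that single structure.

The same pipeline is scriptable from the shell:

```bash
ccfkit --seed 7 simulate --spec examples/toy_organ.yaml --out sim/
ccfkit --seed 7 annotate --sites sim/sites.json --scene sim/scene --method mesh --out annotated.json
ccfkit aggregate --populations sim/datasets.csv --sites annotated.json --out as_pops.csv
ccfkit predict-origin --query sim/datasets.csv --as-pops as_pops.csv --top 3 --out origin.json
ccfkit distances --cells sim/cells.csv --targets Endothelial --out dist.csv --summary summary.csv
ccfkit --seed 7 neighborhoods --cells sim/cells.csv --windows 10,50,100 --ks 4,3,2 --out nb/
ccfkit validate-asctb --table sim/asctb.csv --report report.json
```

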