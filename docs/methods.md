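# Methods

This note records the models, conventions and numerical choices behind
ccfkit, and what the synthetic fixtures do and do not establish about real
atlas data.

## Coordinate frame and cuboid placement

All geometry lives in a right-handed, millimeter, organ-local frame whose
origin is the minimum corner of the reference scene's bounding box. A tissue
block is the unit cube [0,1]³ scaled by its edge lengths, rotated by
intrinsic X→Y→Z Euler angles (degrees; acting on column vectors as
R = Rx·Ry·Rz) about its own minimum corner, then translated. Registration
interfaces in the wild do not document a single Euler convention, so this one
is fixed here and stated explicitly; records produced by other tools may need
a conversion step. Tissue sections carry no geometry of their own: they
inherit the parent block's placement and are stored as count + thickness
metadata.

## Collision detection and intersection volumes

Bounding-box collision uses closed intervals, so face-touching boxes count as
colliding. This matches its role as a fast superset test: every mesh-level
collision is also a bounding-box collision, never the reverse.

Mesh-level intersection volume between watertight meshes supports three
estimators:

* **exact_box** — the analytic overlap product, auto-selected when both
  meshes are axis-aligned boxes (detected by comparing the vertex set to the
  mesh's own bounding-box corners).
* **grid** (default) — the bounding-box intersection of the two meshes is
  tiled with per-axis cell counts ceil(extent/h), where
  h = min(longest bounding-box edge of either mesh) / resolution
  (default 64); cell centers contained in both meshes are counted and
  multiplied by the cell volume. Deterministic at fixed resolution. Using the
  *smaller* mesh's longest edge keeps the result symmetric in the two
  arguments while still scaling the resolution to the tissue block in the
  typical block-vs-organ call. Because the cells tile the box intersection
  exactly, the estimate is exact for axis-aligned box pairs and first-order
  accurate (O(h) boundary error) otherwise.
* **monte_carlo** — uniform samples in the bounding-box intersection with a
  mandatory seed; the hit fraction times the box volume. The standard error
  is V·sqrt(p(1−p)/n).

Estimates are clamped to [0, min of the two mesh volumes].

Point containment is a ray-crossing parity test (Möller–Trumbore) along an
axis-parallel ray. Candidate triangles per ray are pruned with a uniform 2D
grid over the two off-axis coordinates, making batch containment near-linear
in points + faces. Rays that graze an edge, vertex or supporting plane are
flagged and re-cast along the next axis with a tiny seeded origin jitter
(≤ 1e-9 of the mesh diameter, growing per retry) until unambiguous; after
eight attempts the last parity is accepted. Axis-aligned box meshes take an
exact interval-test fast path inside the volume estimators; the generic
ray-parity path is exercised and verified separately against convex
half-space oracles.

Mesh volume is the divergence-theorem sum over faces and requires a
watertight, outward-oriented mesh (every undirected edge used exactly twice,
once per direction; signed volume must be positive).

## Registration records

Extraction sites use a minimal documented JSON dialect (`id`,
`reference_organ`, `operator`, `date`, `dimensions_mm`, `rotation_degrees`,
`translation_mm`, optional `sections` and `annotations`) rather than any
production JSON-LD schema: the atlas literature describes the *content* of
these records, not a canonical layout. Mesh-method collision records carry
intersection volume and fraction-of-block and are sorted by descending
fraction; bbox records are explicitly approximate and carry no volume, and
only mesh records are used for downstream population weighting. Registration
sets serialize with sorted keys so write→read→write is byte-stable.

When structures overlap anatomically, a site's fractions can sum to more
than 1; they are reported as computed and normalized only inside the
population computations.

## ASCT+B tables and crosswalks

The CSV dialect is flat: `AS/n` (+ `/ID`) columns for one partonomy path per
row, `CT/n` for located-in cell types, and `BG/BP/BM/BF/BL` families for the
five biomarker categories (genes, proteins, metabolites, proteoforms,
lipids) — the only categories the validator accepts. Terms without an
ontology id get a deterministic temporary id `ASCTB-TEMP:<slug>` (lowercase,
hyphenated label), with slug collisions disambiguated by a numeric suffix in
first-appearance order. CURIEs are accepted in both `PREFIX:ID` and
`PREFIX_ID` dialects and canonicalized to colon form (an info-level finding,
since the underscore dialect is common in exports). Validation returns
findings, never exceptions, and never mutates its input. Semantic checks
against live ontology services are out of scope; the validator is structural
only.

Crosswalk matching is exact after case-folding and whitespace collapse —
deliberately forgiving because contributing groups do not use standardized
label casing — and unmapped labels receive temporary ids rather than errors.

## Populations: aggregation and prediction

Dataset eligibility mirrors the three atlas-construction criteria: an
extraction site, population data, and QC'd-portal or peer-reviewed
provenance; exclusion reasons cite the first failed criterion in that order.

Aggregation apportions each dataset's counts to its collided structures
proportionally to normalized mesh-intersection fractions. This volume-
weighted mixture is the minimal faithful reading of predicting cell types
from structure annotations plus experimental data; nothing finer-grained
(e.g. within-block gradients) is claimed. Apportioning preserves each
dataset's total count exactly. Mean biomarker expressions are combined as
count-weighted arithmetic means over contributing datasets — the field does
not pin down this choice; count weighting makes the roll-up equal the
per-cell mean when datasets report per-cell averages, which is the
justification used here. Transcriptomics and proteomics are aggregated
separately via a modality filter.

Both predictions operate on proportion vectors, making them invariant to
sequencing depth. Origin prediction compares the query against
anatomical-structure reference vectors by cosine similarity on the union of
their cell-type supports (zeros filled), with ties broken lexicographically
by structure id. Comparing against stored extraction-site vectors instead is
possible by passing those as the reference map; structure-level comparison
is the default universe.

## VCCF distances

Distances are centroid-to-centroid: cell tables carry nucleus centroids, so
no membrane model is attempted. The target set is caller-supplied (e.g.
endothelial labels); by default target-type cells are excluded from the
source side, and when included they are matched to their nearest *other*
target. Ties are broken by lowest target cell id. Units are metadata (µm
default) and never converted implicitly. Comparative healthy-vs-diseased
visualization reduces here to exporting paired summary tables; statistical
testing and rendering are out of scope.

## Multiscale neighborhoods

A window is the index cell plus its n−1 nearest Euclidean neighbors (so a
window of n covers n cells); distance ties are broken by cell-id order. The
default window ladder is (10, 100, 300). Level 1 clusters cell-type
composition vectors; level ℓ>1 clusters the level-(ℓ−1) label compositions
over its window. Clustering is k-means with seeded k-means++ initialization
(n_init 10); the per-level cluster counts are caller-chosen, as no canonical
values exist — the bundled tests use (6, 3, 2) for the three-band
simulation. Published multilevel figures built with other cluster settings
are therefore qualitatively, not numerically, reproducible. The multilevel
graph prepends cell types as level 0; edge weights are the row-normalized
contingency fractions between consecutive levels, so outgoing weights sum
to 1 and per-level node sizes sum to the cell count.

## Synthetic fixtures

All generators are pure functions of (spec, seed); sub-seeds are derived
with crc32-salted SeedSequences so results are stable across processes.

* **Scenes** are nested boxes and ellipsoids (icosahedral subdivision,
  level 4 by default ≈ 0.1% volume error) with an auto-generated partonomy
  table. Containment of children in parents is enforced at bounding-box
  level.
* **Sites** are blocks scaled to 0.3 of their structure's extent, centered
  with optional uniform jitter; at zero jitter each block lies wholly inside
  its structure.
* **Signatures** are Dirichlet draws whose concentration peaks
  (peak 50, background 0.2 by default) occupy disjoint cell-type blocks per
  structure, guaranteeing distinct modes; zero background yields strictly
  orthogonal signatures. Datasets are multinomial samples of the site's
  volume-weighted mixture, optionally perturbed by multiplicative
  lognormal(0, σ) noise before renormalization.
* **Layered tissues** are stacked uniform bands with per-band type mixtures
  and a uniformly sprinkled vascular fraction (5% by default, ~3,000 cells),
  emulating the repeating layered architecture of FTU-bearing tissue.

These fixtures establish estimator correctness, conservation laws and
parameter recovery under known ground truth. They do not establish
performance on real tissue: real anatomical meshes are non-convex and far
finer than toy boxes/ellipsoids, real populations are not Dirichlet-distinct
(adjacent structures share most cell types), cell-type calls are noisy
upstream of this toolkit, and real tissue layers are curved and interdigitated
rather than rectangular. Passing tests therefore demonstrate algorithmic
correctness, not biological validity of any particular atlas.

## Problem sizes used in verification

The bundled verification suite uses 20 random box pairs (grid resolution
128, 2×10⁵ Monte-Carlo samples), 20 fixtures of 500 cells for the distance
oracle, a 4-structure atlas with 200 sampled queries per noise level on the
ladder σ ∈ {0, 0.75, 1.5, 3, 6}, and 5 seeds of the 3,000-cell three-band
simulation. These sizes give comfortable statistical margins (3σ bands,
binomial standard errors) for every assertion while keeping the whole suite
fast on a single CPU.

## Known limitations

* GLB/GLTF reference scenes are recognized but not parsed; structures must
  be exported to OFF/OBJ first.
* The Euler/origin convention may differ from production registration tools
  (undocumented there); round-tripping records between tools needs an
  explicit convention check.
* Grid intersection volumes have O(h) boundary bias on non-box meshes;
  halve h (double the resolution) to quarter-ish the error, or use
  Monte-Carlo with a large sample count for an unbiased estimate with a
  quantified standard error.
* Ontology validation is structural; no reasoning over Uberon/CL is
  performed (a pluggable hook would be needed for semantic checks).
* Mean-expression aggregation assumes a shared biomarker panel per structure
  across contributing datasets and raises otherwise.
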