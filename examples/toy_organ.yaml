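# Toy reference organ with four box structures, plus a layered 2D tissue.
scene:
  organ_id: "UBERON:0000948"
  organ_label: "toy heart"
  extent: [10, 10, 10]
  structures:
    - {as_id: "UBERON:0000001", label: "left wall",  shape: box, center: [2, 2, 2], half_sizes: [1.5, 1.5, 1.5]}
    - {as_id: "UBERON:0000002", label: "right wall", shape: box, center: [7, 2, 2], half_sizes: [1.5, 1.5, 1.5]}
    - {as_id: "UBERON:0000003", label: "septum",     shape: box, center: [2, 7, 2], half_sizes: [1.5, 1.5, 1.5]}
    - {as_id: "UBERON:0000004", label: "apex",       shape: box, center: [7, 7, 7], half_sizes: [1.5, 1.5, 1.5]}
sites:
  per_structure: 1
  jitter: 0.0
datasets:
  n_cells: 2000
  noise: 0.0
tissue:
  bands:
    - {mixture: {TypeA: 0.6, TypeB: 0.4}, y_range: [0, 300]}
    - {mixture: {TypeC: 0.5, TypeD: 0.5}, y_range: [300, 600]}
    - {mixture: {TypeE: 0.7, TypeF: 0.3}, y_range: [600, 900]}
  x_extent: [0, 900]
  vascular_label: "Endothelial"
  vascular_density: 0.05
  n_cells: 3000
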