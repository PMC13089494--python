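# corticolumn

Desk-scale pipeline for comparing cortical cell-type organization across
species — specifically a eutherian (mouse) versus a metatherian (opossum)
primary visual cortex. The package covers the full analysis chain of such
a comparison: reference-annotation repair (3′ UTR extension for sparsely
annotated genomes), single-nucleus QC/embedding/clustering, balanced
cross-species label transfer, archetypal (principal convex hull) analysis
of the intratelencephalic (IT) neuron continuum, laminar statistics of
spatial-transcriptomic cortical columns, and PV/perineuronal-net
immunofluorescence quantification. A synthetic-data generator with ground
truth stands in for deposited animal datasets, so every stage is testable
end to end without downloads.

## Who this is for

Computational neuroscientists and single-cell analysts who need the
*quantitative machinery* of a cross-species column comparison as tested,
reusable functions: the overlap statistic for co-clustered subclasses,
depleting-pool balanced label transfer, elbow-selected polytope fits,
depth-binned Gini confinement indices, extent-normalized density ratios,
partial Spearman permutation tests, and annulus-based WFA enrichment
against depth-matched nulls.

## The core models and statistics

**IT continuum as a polytope.** Multitasking theory predicts that cells
dividing labor over *D* spatial zones lie on a (*D*−1)-dimensional
polytope in expression space; with four cortical layers, IT neurons should
form a tetrahedron in PC space. `pareto.pcha_fit` minimizes
‖Xᵀ − XᵀCS‖² with simplex-constrained C (δ-relaxable) and S by alternating
projected gradient descent; `select_vertex_count` scans K = 2…10 and takes
the chord-distance elbow of explained variance EV(K) = 1 − SSE/TSS.
Archetype-vertex proximity then yields barycentric cell colorings and
per-vertex distances used in the spatial analyses.

**Composition.** Subclass proportions per replicate, with GABAergic
composition the headline contrast (the generator's presets place Pvalb at
50% of GABAergic cells in opossum vs. 35% in mouse); compared by ANOVA +
Tukey HSD + Bonferroni across panels.

**Laminar statistics.** For a pooled, rescaled pseudocolumn with subpial
depth fraction *f* ∈ [0,1]: reflected-KDE density profiles; the Gini index
Σᵢⱼ|cᵢ−cⱼ|/(2BΣc) over B = 20 depth bins (0 = uniform, 0.95 = one bin);
below/above-median density ratios; and partial Spearman correlations of
depth with distance to each polytope vertex, permutation-tested.

**Histology.** Morphological-opening background subtraction (50 µm disk,
99.5th-percentile normalization), arc-length binned PV density and median
WFA intensity along the pial surface, layer-polygon densities, and
per-cell WFA enrichment — median intensity at 5–15 µm minus a 25–50 µm
local background — summarized against a depth-matched spatial null.

See `docs/methods.md` for the full model description, parameter tables,
and numerical choices.

## Worked example

Paired synthetic immunofluorescence fields, one per species preset, with
identical geometry; quantify PV density and PV-centered WFA enrichment:

```python
from corticolumn.synthetic import species_preset, generate_histo
from corticolumn.histo import (
    background_subtract_normalize, layer_densities, pv_pnn_association,
)

for species in ("mouse", "opossum"):
    field, truth = generate_histo(species_preset(species).with_(seed=1))
    corrected = background_subtract_normalize(field)
    dens = layer_densities(field)
    assoc = pv_pnn_association(field, corrected, n_null_per_cell=3, seed=1)
    total = dens["n_cells"].sum() / dens["area_mm2"].sum()
    print(f"{species}: PV density = {total:.1f} cells/mm2, "
          f"WFA enrichment (obs - null) = {assoc['median_difference']:+.3f}")
```

prints

```
mouse: PV density = 301.8 cells/mm2, WFA enrichment (obs - null) = +0.473
opossum: PV density = 361.8 cells/mm2, WFA enrichment (obs - null) = -0.002
```

— the opossum field carries ~20% more PV cells per mm², and its WFA rings
(placed at random deep-layer sites in the opossum preset) show no
enrichment around PV somata, while the mouse preset's PV-centered rings
produce a strongly positive median difference.

The same stages are scriptable from the shell:

```
corticolumn simulate --species opossum --n-cells 2000 --outdir data/
corticolumn all --seed 0 --outdir out/        # atlas + spatial + histology
```

`corticolumn all` writes `out/report.json` plus per-stage TSV tables
(GABAergic proportions, subclass–cluster overlap, confusion matrices,
Gini indices, layer densities).

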