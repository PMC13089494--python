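# Methods

`corticolumn` re-implements, at desk scale and against synthetic data, a
cross-species comparison of cortical cell-type organization between a
eutherian (mouse) and a metatherian (opossum) primary visual cortex: the
composition of GABAergic interneurons, the archetypal geometry of the
intratelencephalic (IT) neuron continuum, the laminar statistics of a
spatial cortical column, and the quantification of parvalbumin (PV) neuron
density and perineuronal-net (WFA) localization in immunofluorescence.
This note records the models, parameters, numerical choices, and the
limits of what the synthetic tests demonstrate.

## Synthetic data model

The generator (`corticolumn.synthetic`) is the package's substitute for
deposited animal datasets; its defaults define the study conditions that
all recovery tests and the acceptance script run under.

**Expression.** Every cell draws a latent expression vector over `n_genes`
genes. A shared per-gene baseline (`0.6 + 0.5·N(0,1)` on the latent scale)
creates realistic between-gene abundance variation. Discrete subclasses
(non-IT glutamatergic: L5PT, L5NP, L6CT, L6b; GABAergic: Pvalb, Sst, Vip,
Lamp5, Frem1; non-neuronal: Astro, Oligo, OPC, Micro) add +3.0 to their
own marker block (block size scales with the panel, 4–40 genes). IT cells
instead mix four archetype programs — one per modeled layer (2/3, 4, 5, 6)
— with Dirichlet weights `w ~ Dir(α)`; the latent vector is `w·A` plus
Gaussian noise (`noise_sd`, default 0.15). Counts are negative-binomial:
gene rates are `softplus(latent)` normalized per cell, library sizes are
log-normal (median 6,000 UMIs for the mouse preset, 3,000 for opossum —
the platform/species depth contrast), and sampling is gamma–Poisson with
shared shape `nb_dispersion = 4`.

**Species presets** differ only in:

| field | mouse | opossum | models |
|---|---|---|---|
| `archetype_concentration` | (0.3, 0.3, 0.3, 0.3) | (1.0, 1.0, 1.0, 0.25) | vertex-peaked vs. face-spread IT continuum |
| `gabaergic_proportions` (Pvalb) | 0.35 | 0.50 | interneuron composition shift |
| `mean_log_umis` | ln 6000 | ln 3000 | sequencing-depth difference |
| `pv_density_per_mm2` | 300 | 360 | ~20% PV density excess |
| `pnn_mode` | `pv_centered` | `deep_layer_random` | WFA ring localization |

The opossum concentration vector spreads IT mass across the face spanned
by the first three archetypes (generalist identities) while the mouse
preset piles cells near all four vertices (specialists). The absolute PV
densities are generator choices of realistic magnitude; only their ratio
(1.2) is a modeled quantity. Noise levels and dispersions are calibration
choices — neither platform's noise is quantitatively specified anywhere —
fixed once at values that leave the four-archetype geometry recoverable by
the pipeline, which is the regime the analysis operates in on real data.

**Spatial columns.** Cells occupy a 300 µm × 1,000 µm column (top of layer
2/3 to bottom of layer 6); each subclass draws depth from a truncated
normal law (µ, σ in µm, e.g. L4-like cells at 380 ± 90). IT archetype
weights covary with depth through a Gaussian kernel (bandwidth 160 µm)
over the archetypes' home-layer depths, concentrated by a Dirichlet with
κ = 25, so the transcriptomic continuum is spatially graded as in tissue.
Spatial counts reuse the atlas machinery at 0.15× depth (cell bins capture
far fewer molecules than nuclei libraries).

**Histology fields.** A 2 mm × 2 mm single-channel image at 4 µm/px with a
linear depth ramp background plus Gaussian noise (σ = 0.02). PV centroids
follow a Poisson process with layer-modulated intensity (layers 4/5
richest). `pv_centered` paints annular intensity (+0.6) at 5–15 µm around
each PV centroid; `deep_layer_random` paints the same number of rings at
uniform deep-layer (lower 55%) sites more than 20 µm from any PV cell.

**What the generator does not emulate:** ambient RNA, doublets, batch
chemistry, read-level structure, segmentation error, tissue curvature, or
non-trivial pial geometry (the pial surface is the top edge). Passing
recovery tests therefore demonstrate that the analysis code measures what
it claims under the stated generative model — not that the biological
conclusions would survive those real-data artifacts.

## Single-nucleus core

QC keeps cells with detected genes strictly inside (700, 6,500) and UMI
totals strictly below 40,000, then genes detected in ≥ 9 surviving cells.
Normalization is log-CP10K (`ln(1 + 10⁴·count/total)`); the SCTransform
normalization used by the original pipeline is out of scope here, and all
downstream operations require only a normalization with stored per-gene
centering/scaling for out-of-sample projection. Highly variable genes are
ranked by standardized dispersion: variance/mean of the depth-normalized
counts, z-scored within 20 equal-width bins of gene mean, ties broken by
gene id. PCA standardizes genes (values clipped at ±10 SD), uses exact SVD
below 500 cells/genes and seeded randomized SVD above, and fixes component
signs by the largest-magnitude loading. Balanced PCA fits loadings on a
per-label downsample (default: smallest label's size) and projects all
cells. Clustering is Leiden (RB-configuration, resolution-parameterized,
seeded) on an undirected kNN graph.

Depth matching draws a target total per cell from the donor's empirical
UMI distribution and subsamples molecules **without replacement**
(multivariate hypergeometric). This preserves the cell's relative profile
in expectation, makes the downsampled total exact, and guarantees no count
increases; with-replacement multinomial resampling would violate the
last property.

Differential expression: two-sided rank-sum P on log-normalized values,
log2 fold change on depth-normalized counts (`expm1` scale — fold changes
computed on log-scale means compress 10× differences below any useful
threshold), detection fraction `pct1` from raw counts. Default filters
log2FC > 0.75, pct1 > 0.25, raw P < 0.05; a Benjamini–Hochberg column is
reported but not used to filter.

## Cross-species comparison

Genes are restricted to strictly one-to-one orthologs and re-named to the
reference species. Integration z-scores each dataset per gene, runs joint
PCA, and applies one global shift per dataset — the mean displacement over
mutual-nearest-neighbor pairs (k = 20) toward the largest dataset. This is
a deliberately minimal, fully specified stand-in for anchor-based
integration: the downstream statistics need only a shared embedding with
the batch offset reduced.

Subclass relatedness in the joint space is the cluster-overlap statistic
`O(i,j) = Σ_c min(n_ic/n_i, n_jc/n_j)` — the shared mass of two
subclasses' cluster distributions, 1 iff identical, 0 iff disjoint.

Label transfer is balanced and iterative: each iteration draws at most
`cap` (100) cells per subclass from a per-subclass pool that depletes
without replacement across iterations and resets when exhausted (every
reference cell is used once before any is reused); an embedding is fitted
on the draw, the query projected, and the `k_vote` = 30 nearest reference
cells vote with inverse-distance weights. Probabilities average over
iterations; the label is the argmax with lexicographic tie-break. The
voting rule is the package's choice — the transfer mechanism behind the
original pipeline's probabilities is not specified beyond "dims = 1:30".

## Polytope geometry

`pcha_fit` is a from-scratch implementation of the principal convex hull:
minimize `‖Xᵀ − XᵀCS‖²` with C columns on the (δ-relaxed) simplex and S
columns on the simplex, by alternating projected-gradient descent with
per-block adaptive step sizes, furthest-sum initialization, and
accept/reject line search — SSE is non-increasing by construction, and a
monotonicity assertion runs in the test suite. Explained variance is
`1 − SSE/TSS` with TSS the squared deviation from the data mean (the data
are centered internally). Defaults: `max_iter` 250, relative SSE tolerance
3 × 10⁻⁶, five seeded restarts in the vertex-count scan — at these
settings noise-free simplex mixtures are recovered to well under the 0.05
test tolerance and a full 2–10 vertex scan of a 2,000-cell embedding runs
in ~20 s.

Vertex-count selection is a chord-distance elbow on (K, EV): the candidate
furthest from the line joining the first and last candidates, endpoints
excluded, near-ties resolved to the smallest K. δ = 0 for tetrahedron
scans and δ = 0.1 for the spatial triangle fit.

A fundamental sampling fact constrains recovery tests: with δ ≤ 0.1 the
archetypes are confined to (near) the convex hull of the data, and for
*uniform* Dirichlet sampling at n = 500 the true vertices sit 0.05–0.27
away from that hull (worse for more vertices). Recovery-to-0.05 assertions
therefore use vertex-concentrated mixtures (Dirichlet 0.3); for uniform
samples the test compares the fit against the hull-projection optimum
(an NNLS oracle) instead.

The continuum-vs-gap shuffle test projects two putative subclasses onto
the axis joining their centroids and computes T = (KDE minimum between the
subclass medians) / (smaller median-point density); the null permutes each
gene independently within each subclass. T ≈ 1 flags a genuine continuum,
T ≈ 0 a gap; `p = (1 + #{T_null ≥ T_obs})/(1 + n_shuffles)`. This statistic
is this package's own fully specified construction for the
continuum-vs-noisy-discrete question; it is not a reproduction of any
previously published shuffling procedure.

## Spatial column statistics

Stereo-style QC keeps cells with ≥ 50 detected genes and ≥ 100 UMIs and
converts chip units to µm (2 units/µm). ROIs pool into a pseudocolumn by
rescaling each ROI's width and height to the largest ROI's. Multi-round
kNN assignment integrates the unassigned query cells with the reference
each round (round 1 downsamples the reference to the query count; rounds
2–3 use the full reference — the alternative, re-downsampling each round,
is the one undocumented fork here), assigns when the plurality label among
k = 50 neighbors reaches the round threshold (class: 100/100/75%;
subclass: 100/75/50%), with plurality ties left unassigned that round.

Laminar statistics operate on the normalized subpial fraction: Gaussian
KDE profiles with boundary reflection at 0 and 1 (bandwidth 0.05);
a Gini index over 20 equal-width depth bins,
`Σ_ij |c_i − c_j| / (2 B Σ c)` (0 = uniform, (B−1)/B = single-bin
confinement); and an extent-normalized below/above density ratio split at
the reference subclass's median depth (counts divided by region extent, a
density rather than raw counts, matching the measure's name). Depth–axis
partial Spearman correlations use the rank-space identity
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` with a permutation
null that shuffles depth only, keeping the two vertex-distance variables
paired; two-sided p with the +1 correction.

## Histology metrics

Background correction opens the image with a 50 µm disk (grayscale
morphological opening), subtracts, clips at zero and normalizes to the
99.5th percentile of corrected signal inside the cortical mask — constant
offsets vanish exactly, structures smaller than the disk survive.
Arc-length profiles project centroids and cortical pixels to the nearest
point of the (densely resampled) pial polyline; densities are counts per
bin area in mm², intensities are per-bin medians (missing for empty bins).
Layer densities count centroids inside each layer polygon (boundary points
go to the first layer in declared order) divided by polygon area.

PV–PNN association: per PV cell, enrichment = median corrected intensity
in the 5–15 µm annulus minus the median in a 25–50 µm background annulus
(the background annulus extent is this package's parameter choice, exposed
as arguments). The null samples points at depths drawn from the PV depth
distribution (± 5 µm jitter), uniformly along the pial arc, at least
15 µm from any PV centroid; cells or null points whose background annulus
leaves the mask are censored symmetrically. The summary is
median(observed) − median(null): positive iff WFA rings preferentially
surround PV cells, and calibrated to ~0 when rings are placed
independently of PV positions at matched depths (the statistic's defining
null property, asserted in the tests).

## Inference

Group comparisons: one-way ANOVA per measurement family, Tukey HSD
(studentized range) over group pairs, Bonferroni multiplication across
families capped at 1. The rank-sum test is exact (permutation
distribution) for pooled n ≤ 50 without ties — complete separation at
n = 3 vs 4 gives the minimal two-sided p = 2/35 ≈ 0.0571 — and a
tie-corrected normal approximation otherwise. Spearman correlation is
Pearson on average ranks.

## Problem sizes

The recovery analyses run at: 20 IT datasets of 2,000 cells × 300 genes
for the vertex-count mode; 5 atlases per species of 10,000 cells × 2,000
genes (with one shared 10,000-cell labeled reference per species and 20
transfer iterations) for composition recovery; 5 paired 2 mm × 2 mm
histology fields for the density contrast. These sizes put every
recovered quantity's sampling error comfortably inside its comparison
tolerance (e.g. the binomial SD of the Pvalb fraction at ~2,000 GABAergic
cells is ~1.1 percentage points against a 3-point tolerance) while keeping
a full run on a single CPU core in the tens of minutes.

## Known limitations

- The generator's archetype programs are block-structured and orthogonal;
  real layer programs share genes, which would lower label-transfer
  accuracy and blur the elbow.
- The MNN-shift integration removes one global offset per dataset; it
  cannot correct nonlinear batch distortions.
- The continuum shuffle statistic depends on the KDE bandwidth (scipy's
  Scott rule) near the tails; it is a screening statistic, not a
  calibrated test of manifold topology.
- The pial surface is assumed well-approximated by an ordered polyline
  with the tissue on one side; strongly folded cortex would need geodesic
  depth, which is not implemented.
- GTF handling covers gene records only; transcript-level 3′ UTR
  structure is reduced to `has_utr3`/`utr3_length` attributes.
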