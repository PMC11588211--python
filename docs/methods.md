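# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## Model

### Spatial graph

Spots are connected to their K nearest neighbors by Euclidean distance in
metric (full-resolution pixel) coordinates — array row/column indices are
not used because KNN presumes a metric space. The directed KNN relation is
symmetrized by **union** (an edge exists if either endpoint selected the
other). Union was chosen over mutual-KNN because mutual intersection can
isolate boundary spots, and an isolated spot would have no microenvironment
beyond itself. Exact distance ties (common on regular grids) are broken by
smaller node index, which makes the graph — and everything downstream —
reproducible. Default K = 6 matches the hexagonal packing of Visium spots.

Derived operators: normalized adjacency `Â_norm = D̂^(-1/2)(A+I)D̂^(-1/2)`
(spectral radius ≤ 1, so deep GCN stacks cannot blow up) and combinatorial
Laplacian `L = D − A` (rows sum to zero, which is what makes diffusion
mass-conserving).

### Feature augmentation

`F = Eg ⊕ Ei ⊕ Es`, column-wise concatenation with each block z-scored per
column first so no modality dominates by scale.

* **Eg** — library-size normalization to the median depth, `log1p`, top
  `n_hvg` (default 3000) highest-variance genes (ties by gene order),
  z-scoring. All-zero spots stay zero vectors with a warning rather than
  erroring, since tissue-edge spots with no counts do occur.
* **Ei** — per-spot patches cropped from the slide image, centered on the
  spot with edge windows shifted inward so every patch has identical shape.
  The default extractor (`patchstats`) computes per-channel mean, variance
  and an 8-bin histogram (30 features): deterministic, dependency-free, and
  sufficient for stain-intensity differences between regions. A pretrained
  CNN can be registered as an alternative backbone (`register_backbone`);
  features wider than `d_i` (default 50) are SVD-compressed.
* **Es** — the Katz matrix `K = (I − βA)^(-1) − I` scores each spot pair by
  attenuated path counts (β default 0.1; if β ≥ 1/ρ(A) it is shrunk to
  0.9/ρ(A) so the series converges). K is N×N, so row i is compressed to a
  fixed-width per-spot feature by keeping the `d_s` = 32 dominant singular
  directions scaled by their singular values; as K is symmetric this is an
  exact eigendecomposition, with singular-vector signs fixed for
  reproducibility. 32 columns retain the dominant global structure at any
  slide size while keeping the fused width stable.

Dropping `Ei` or `Es`, or fusing `Eg` alone, are first-class configuration
switches (the without-image / without-Katz / without-fusion ablations).

### Diffusion microenvironments

For each spot i, a unit source `e_i` is diffused through the heat kernel
`exp(−αL)`; all rows are obtained at once as the matrix exponential
(dense `scipy.linalg.expm` up to N = 3000, action-of-exponential beyond).
The kernel is symmetric, entrywise nonnegative, and doubly stochastic for a
combinatorial Laplacian, so signal mass is conserved and spreads outward.
Spots are ranked by accumulated signal (descending, index tie-break) and the
top `N_sub` form the microenvironment. Defaults: α = 0.1 (gentle spread —
roughly nearest-ring dominance on a K = 6 graph), `N_sub` = 20 (about three
rings). A fixed membership size rather than a signal threshold keeps the
readout average well defined everywhere, including near tissue boundaries.
Microenvironments are computed once from the clean topology and reused for
the corrupted branch, because corruption shuffles features, not edges.
Setting `N_sub = N` turns the readout into a single whole-graph summary —
exactly the without-signal ablation (classic DGI readout).

### Contrastive graph autoencoder

Encoder: two GCN layers `act(Â_norm · H · W + b)` with ReLU, widths
d → 512 → 64; decoder mirrors them (64 → 512 → d) with a linear final layer
so reconstructed features can be negative. Reconstruction loss is the mean
per-spot squared error (the sum variant is available via
`rec_reduction="sum"`); the mean keeps the α = 1 weighting stable across
slide sizes.

Contrastive objective: microenvironment summaries
`S_i = σ(mean_{j∈env(i)} h_j)` (logistic σ squashes into (0,1)); bilinear
discriminator `D(h,s) = σ(hᵀWs)` scored in logit space; binary cross-entropy
with positives `(h_i, S_i)` and negatives `(h′_i, S_i)` where `h′` comes
from encoding a row-permuted feature matrix on the unchanged graph — one
negative per spot. The symmetric term swaps roles: positives `(h′_i, S′_i)`,
negatives `(h_i, S′_i)`. Total loss `L = α·L_rec + β·(L_con + L_con′)` with
α = β = 1 by default.

Training: full-batch Adam (lr 1e-3, weight decay 1e-4 on weight matrices),
500 epochs, Glorot-uniform initialization, a fresh corruption permutation
each epoch — all drawn from one seeded generator, so a run is a
deterministic function of its config. The network and all gradients are
hand-written NumPy; analytic gradients are pinned against central finite
differences in the test suite. Non-finite losses abort with the diverging
term named.

### Clustering and metrics

k-means (20 restarts) is the default clusterer, with GMM and Leiden options.
ARI, NMI (arithmetic-mean normalization — variants differ, so this is
stated), V-measure and Purity are computed from the contingency table of
the two partitions; the test suite cross-checks them against scikit-learn
to 1e-10. Silhouette and Davies–Bouldin come from scikit-learn directly.
No spatial smoothing of labels is applied.

## Synthetic data

The generator emulates an annotated Visium slide: a regular grid of spots,
domains as contiguous vertical bands (cortical-layer-like; a Voronoi
"mosaic" layout is available for tumor-like mixtures), disjoint marker-gene
sets per domain whose means are raised by `exp(marker_log_fc)`,
negative-binomial counts (Var = μ + φμ², gamma–Poisson sampling) with
lognormal per-spot depth, and a slide image whose spot footprints are tinted
by a per-domain base color blended with a neutral tissue tone by
`image_domain_contrast` plus Gaussian pixel noise. Defaults (10×30 grid,
3 domains, 300 genes, 30 markers/domain, log-FC 1.5, dispersion 0.3, mean
depth 2000, full image contrast) describe a clearly layered, moderately
overdispersed slide — roughly a small DLPFC-like benchmark.

What it does **not** emulate: cell-type mixtures within spots, lateral
transcript diffusion, platform artifacts, stain variation, irregular tissue
boundaries, or realistic gene–gene correlation. Passing the end-to-end
recovery test therefore shows the pipeline extracts and integrates the
signal the generator planted — not performance on real tissue.

Two regimes are used by the verification suite, chosen for what they probe:

* **Null**: `marker_log_fc = 0` *and* `image_domain_contrast = 0` — no
  domain signal in any modality. The pipeline should find nothing
  (ARI ≈ 0). The image contrast must be zeroed too: a tinted image is
  itself domain signal, and with it present the image block alone recovers
  the domains.
* **Hard**: `marker_log_fc = 0.8` with an uninformative image
  (`contrast = 0`). With the full-contrast image every variant saturates at
  ARI ≈ 1 and comparisons are ceiling-limited; the hard regime keeps ARI
  below saturation so that ablation orderings (e.g. per-node
  microenvironment readout vs a single whole-graph summary) are measurable.

## Numerical choices and limitations

* Dense matrices throughout up to N ≈ 3000–4000 per operator (exact KNN with
  tie-stable ranking ≤ 4096; dense matrix exponential ≤ 3000), with sparse /
  action-of-exponential paths beyond; results agree within solver tolerance.
* Problem sizes in the tests and the verification script (≤ 50-node oracle
  graphs, 300-spot end-to-end runs, three replicate seeds) were chosen as
  the smallest instances that still exercise every code path and give stable
  stochastic outcomes.
* Full-batch training holds the N×N kernel and membership matrices in
  memory; very large slides (N ≫ 10⁴) would need mini-batching, which is
  out of scope here.
* The pretrained-CNN image backbone is an interface only; no weights ship
  with the package.
* Defaults that the source method leaves unstated (encoder widths, optimizer,
  loss weights, β for Katz, `N_sub`, per-block standardization) are this
  package's choices, documented above and exposed in `RunConfig`.
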