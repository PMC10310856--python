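# Methods

## Network propagation

The interactome is an undirected simple graph over canonicalized gene
identifiers (upper-cased, whitespace-stripped strings; no identifier-mapping
service is consulted). Edge tables carrying a confidence score are filtered
with a strict inequality, `score > threshold` (default 0.75, matching
high-confidence STRING-style usage); scoreless tables (BioGRID/IntAct-style)
contribute all edges, and duplicate observations of an edge keep the maximum
score before thresholding. Self-loops and duplicates are removed.

Seed weights are −log10 of association p-values, maximized over redundant
rows and pooled traits. Propagation solves x = (1−d)·p + d·Wᵀx by power
iteration on the sparse column-stochastic adjacency, with p the seed weights
normalized to a probability vector. Walk mass reaching a degree-zero node
restarts through p (the standard dangling-node convention), so the scores
remain a probability distribution. Defaults: damping d = 0.85 (the
conventional PPR value; the source workflow does not pin one), L1 tolerance
1e−12, 1000 iterations; non-convergence raises with the residual. On graphs
of ≤ 50 nodes the iterate agrees with the dense solve of
(I − d·Wᵀ)x = (1−d)·p to better than 1e−10 (tested), and with networkx's
implementation to 1e−8.

Selection takes the ⌈fraction·N⌉ highest-scoring nodes (default fraction
0.25). Ceiling rather than floor keeps the selection non-empty for any
positive fraction; ties at the cutoff break lexicographically so the
selection is deterministic and invariant to monotone rescaling of scores.

## Module discovery and significance

The selected nodes' induced subgraph is partitioned by walktrap (igraph,
walk length 4 — the algorithm's canonical default, config-exposed).
Communities above `max_size` (default 300) are re-clustered on their induced
subgraph, recursively (depth cap 20). A community walktrap cannot split
(single-community clustering) is kept and flagged `unsplittable` with a
warning rather than discarded, so no genes silently vanish. Communities of
more than `min_size` (default 10) genes are reported as modules.

Each module's member propagation scores are compared with the scores of all
other nodes in the *selected* subgraph by a two-sample KS test, one-sided in
the "members stochastically greater" direction (module significance means
enrichment in propagation signal; two-sided available via config). The
background choice matters: testing against the whole interactome would make
any module of selected nodes "significant" purely through the selection step,
so the within-selection background is the calibrated default; `background="all"`
remains available. Raw p-values are BH-adjusted across the modules of one
trait's run (not pooled across traits), flagged at α = 0.05.

Calibration and power are tested empirically (see `tests/test_acceptance.py`):
under a null with uniformly placed seeds on an Erdős–Rényi graph
(200 replicates, 300 nodes, 30 seeds), the significant-module rate stays
below 0.07; with the generator defaults (below), a planted seed-enriched
community is recovered as significant — judged both per-module (≥ 80%
purity) and on the significant-gene union (precision and recall ≥ 0.8) — in
≥ 95 of 100 replicates. Walktrap legitimately splits a dense
internally-unstructured block into sub-modules, which is why recovery is
also judged at the union level: the union of significant-module genes is the
quantity consumed downstream.

## Cross-disease overlap and enrichment

Disease-level similarity is the Jaccard index between significant-module
gene unions; a trait without significant modules contributes a zero
row/column (warned). Module groups link significant modules of *different*
traits at Jaccard ≥ 0.7 (inclusive, config-exposed; within-trait pairs never
link) and take connected components spanning ≥ 2 traits — single-link
closure, chosen over all-pairs cliques as the more permissive and simpler
reading of "groups of overlapping modules". Fisher enrichment is one-sided
over-representation on the 2×2 table, BH-adjusted across tested terms; terms
without background hits are skipped; the background defaults to the caller's
gene universe and is always explicit in the API.

## Benchmarking

The above-Q3 gold standard uses the type-7 (linear interpolation) quantile —
the default of numpy and R — with strict `score > Q3`; if all scores tie the
set is empty (warned) and the max-score set holds every gene. Negatives are
all scored genes outside the positive set. AUC is the Mann–Whitney identity
with ties counted ½, which equals the trapezoidal area under the stepwise
ROC curve exactly (tested to 1e−12, and against scikit-learn).

## Multi-omics integration

Significance A follows the canonical Perseus definition: with r₀ the median
and r₁/r₋₁ the 84.13th/15.87th percentiles, z = (r−r₀)/(r₁−r₀) above the
median (mirrored below), p = ½·erfc(z/√2). It requires ≥ 8 finite ratios and
non-degenerate percentile spreads. The triple overlap intersects the
significant-module gene unions of the GWAS, transcriptome and proteome
expansions; candidates are triple-overlap genes with p < α (default 0.05) in
*both* omics layers and sign-concordant log2 ratios. No fold-change magnitude
cutoff is applied (none is pinned by the source workflow); transcript
p-values are taken from the input table, not recomputed.

## Morphometrics

*Form factor.* FF = 4π·area/perimeter²; 1 for a circle by the isoperimetric
equality, scale-invariant. For masks, area is the foreground pixel count
× pixel_size² and the perimeter is the length of the marching-squares
contour at level 0.5 after Gaussian pre-smoothing of the binary mask
(σ = 1 px, config-exposed; σ = 0 disables). Raw marching squares on a hard
binary disk overestimates the perimeter by ~5% (staircase bias), pushing a
disk's FF to 0.90; the light smoothing removes that bias (disk FF 0.991,
side-38 square FF 0.822 vs π/4 = 0.785). The trade-off, documented rather
than hidden, is corner rounding: sharp convex corners of objects smaller
than ~20 px bias FF upward (a 10×10 square reads ≈ 0.94), so tests use
≥ 38 px shapes. Real cell outlines are smooth at this scale, which is the
regime the estimator is tuned for. The mask must contain exactly one
8-connected component.

*Density profiles.* Particle distances from the process tip are binned into
half-open [i·w, (i+1)·w) bins (default 1 µm over 15 µm); a particle exactly
at the segment boundary is excluded. Densities are counts over the supplied
per-bin volumes (volume estimation from image stacks is out of scope —
volumes are inputs). Straight-line distance is assumed for synthetic data;
curvilinear distance along skeletonized processes is not implemented.

*Orientation dispersion.* Per-pixel structure orientation comes from the
intensity gradient (structure ⟂ gradient; y axis up, angles counterclockwise
from the x axis on [−90°, 90°)), accumulated into a gradient-energy-weighted
histogram (2° bins, config-exposed). A Gaussian (amplitude, mean, sigma,
baseline) is least-squares fitted with circular wrap-around; the dispersion
factor is |sigma| in degrees and the goodness is R² clipped to [0, 1]. Two
numerical choices matter: the baseline is bounded above by the histogram
minimum (it models the isotropic floor, which cannot exceed the smallest
bin — an unconstrained baseline lets a flat histogram be "fit" by a noise
spike), and the fit is multi-started from a deterministic list of widths
(data-driven circular spread first) because a near-delta histogram from a
noiseless grating defeats any single start. Gratings recover their generated
angle within ~1° and disperse < 1°; white noise yields dispersion ≫ 30° with
R² < 0.3.

*Tracks.* The primary speed statistic is mean frame-to-frame speed (path
length over elapsed time); net displacement over total time is also exposed
(`track_net_speed`) since the two diverge for curved tracks and the source
workflow does not specify which its tracker reported.

## Synthetic data

Generators are pure functions of their spec and `rng_seed` (byte-identical
reruns, tested) and attach machine-readable ground truth.

*Interactome.* A stochastic block model — chosen over degree-corrected
variants for analytic tractability of expected edge counts (tested against
binomial moments); defaults 10 blocks × 50 nodes, p_in = 0.2, p_out = 0.01.
The block must be small relative to the top-25% selection for the
within-selection significance test to have a contrast, mirroring the real
regime where the selected quarter of an ~18k-node interactome vastly exceeds
any single disease module; 50-node blocks in a 500-node graph (selection
125) preserve that ratio at desk scale. Seeds: 10 genes per seeded block
with weights |N(3,1)| (mimicking the dynamic range of −log10 GWAS p-values
without claiming realism) plus 10 weak background seeds (|N(1,0.5)|)
scattered over the other blocks, as real GWAS hits scatter across the
genome. Graphs whose giant component covers < 90% of nodes are regenerated
(≤ 10 attempts, warned).

*Omics tables.* Planted genes get log2 ratio ±effect (default 2.0) plus
N(0, 0.3) noise, sign-shared across layers for a configurable concordant
fraction; null genes are independent N(0, noise_sd) per layer; p-values are
two-sided z-tests against the known noise sd. Under a pure null,
candidate selection returns ≈ α²/2 of the universe (tested).

*Images and tracks.* Shape masks (disk/square/rectangle/star) carry analytic
area/perimeter metadata; orientation textures are sinusoidal gratings with
known angle plus Gaussian noise; tracks move in straight lines at exactly
the requested speed.

What the generators deliberately do not emulate: scale-free degree
distributions, linkage-disequilibrium structure among GWAS hits, correlated
noise between omics layers, imaging point-spread functions and segmentation
errors. Passing tests therefore demonstrate correctness and calibration of
the algorithms under clean modular structure, not performance on real
interactomes or micrographs.

## Problem sizes

The test suite and acceptance script run everything at desk scale: graphs of
300–2,000 nodes, 100–200 replicate simulations for the calibration checks,
256² rasters, 10⁵-sample Monte-Carlo for the Significance A tail. These sizes
keep every statistic's Monte-Carlo error well inside its asserted tolerance
while the full suite completes in a couple of minutes.

## Known limitations

- Identifier handling is purely syntactic; cross-database ID mapping is the
  caller's responsibility.
- The KS test treats member scores as an i.i.d. sample; propagation scores
  of adjacent genes are correlated, which the empirical calibration test
  bounds (rate ≤ 0.07) but does not remove.
- The whether-to-recluster rule follows community *size* only, as specified;
  no modularity or density criterion is applied.
- Perimeter estimation trades corner fidelity for curvature fidelity (see
  above); FF values of sub-20-px objects should not be compared against
  analytic expectations.
- The dispersion estimator approximates the Fourier-components orientation
  method with the gradient structure tensor; absolute sigma values differ
  slightly from ImageJ's plugin, comparisons should stay within one
  estimator.
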