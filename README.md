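# glianet

Network-propagation discovery of disease gene modules, multi-omics candidate
selection, and quantitative cell morphometrics — a reusable implementation of
a proteogenomic-cellular analysis workflow for neurodegenerative disease,
with a synthetic-data module so every stage can be exercised and validated
without any database downloads.

**Who it is for.** Computational biologists who want to (i) expand GWAS hit
lists over a protein–protein interaction network into significant gene
modules, (ii) compare such modules across diseases and omics layers, and
(iii) quantify cell-shape and intracellular-transport phenotypes (e.g.
astrocyte process arborization, kinesin cargo distribution) from image-derived
measurements.

## The methods at the core

**Network expansion.** Seed genes carry weights w(g) = −log10 p from
association tables (the strongest association wins when a gene repeats;
traits can be pooled). Weights are diffused over the interactome by
Personalized PageRank: the stationary solution of

    x = (1 − d)·p + d·Wᵀx

with restart vector `p` (normalized seed weights), column-stochastic
adjacency `W` and damping `d = 0.85`. The top 25% of nodes by score are
clustered with walktrap; communities above 300 nodes are re-clustered
recursively, and communities of more than 10 genes become *modules*. A module
is *significant* when its members' propagation scores are stochastically
greater than the remaining selected nodes by a one-sided two-sample
Kolmogorov–Smirnov test, Benjamini–Hochberg adjusted at α = 0.05.

**Cross-disease and multi-omics integration.** Disease similarity is the
Jaccard index J(A,B) = |A∩B| / |A∪B| between significant-module gene unions;
modules of different traits with J ≥ 0.7 are chained into shared-module
groups; gene-set enrichment uses the one-sided Fisher exact test with BH
control. Protein log2 ratios are scored with the Significance A outlier
statistic (asymmetric robust z from the 15.87/50/84.13 percentiles,
p = ½·erfc(z/√2)), and candidates are triple-overlap genes with
sign-concordant, significant changes at both transcript and protein level.

**Benchmarking.** Gold standards come from association-score tables (genes
strictly above the third quartile; the maximum scorers) or curated lists
(drug targets); ranking quality is the ROC AUC by the Mann–Whitney
pair-counting identity.

**Morphometrics.** Form factor FF = 4π·area/perimeter² (1 for a circle, → 0
for arborized outlines; sub-pixel marching-squares perimeter), distance-binned
particle density profiles (1 µm bins over the distal 15 µm of a process),
volume-ratio densities, percent area overlap between masks, an
orientation-dispersion factor (sigma of a Gaussian fitted to the
gradient-energy-weighted orientation histogram), and mean frame-to-frame
track speed.

## Worked example

```bash
python examples/02_module_discovery.py
```

prints (abridged):

```
trait 'planted': 3 modules (1 significant at BH 0.05)
size  KS D   p_raw     p_adj     significant
  47  0.574  7.47e-10  2.24e-09  True
  13  0.027  9.64e-01  9.90e-01  False
  16  0.009  9.90e-01  9.90e-01  False
significant-module gene union vs planted community: precision 0.96, recall 0.90
```

A 500-gene interactome is generated with ten planted communities and seed
weights concentrated in one of them. The pipeline finds three candidate
modules among the top-25% propagated nodes; only the one carrying the seed
signal survives the KS+BH filter (D = 0.57, adjusted p ≈ 2×10⁻⁹), and its
genes recover the planted community at 0.96 precision / 0.90 recall — the
module the method reports is the planted disease community, not an arbitrary
cluster. The other `examples/*.py` scripts walk through expansion,
cross-disease overlap, benchmarking, multi-omics candidate selection and the
morphometric statistics in the same style.

A thin command-line interface mirrors the library
(`glianet build-net | seeds | expand | modules | overlap | enrich |
benchmark | morpho …`); run `glianet --help`.

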