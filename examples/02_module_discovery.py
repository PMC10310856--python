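"""Discover significant disease modules in one pipeline call.

Runs propagation, top-fraction selection, iterative walktrap clustering and
KS+Benjamini-Hochberg module scoring on a synthetic interactome with one
seed-enriched community, then prints each module with its enrichment
statistics and how well the significant modules recover the planted block.
"""

from glianet import (
    PipelineConfig,
    PlantedNetworkSpec,
    discover_significant_modules,
    make_planted_interactome,
)

spec = PlantedNetworkSpec(rng_seed=42)
graph, block_of, seeds = make_planted_interactome(spec)
catalog = discover_significant_modules(graph, seeds, PipelineConfig())

print(f"trait '{catalog.trait}': {len(catalog.modules)} modules "
      f"({len(catalog.significant_modules)} significant at BH 0.05)")
print("size  KS D   p_raw     p_adj     significant")
for m in catalog.modules:
    print(f"{len(m.genes):4d}  {m.ks_statistic:.3f}  {m.p_raw:.2e}  "
          f"{m.p_adjusted:.2e}  {m.significant}")

planted = {g for g, b in block_of.items() if b == spec.seed_blocks[0]}
union = catalog.all_module_genes
if union:
    precision = len(union & planted) / len(union)
    recall = len(union & planted) / len(planted)
    print(f"significant-module gene union vs planted community: "
          f"precision {precision:.2f}, recall {recall:.2f}")
# High precision/recall means the significant modules are the planted disease
# community, i.e. the KS test singled out the communities rich in propagation
# signal rather than arbitrary clusters.
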