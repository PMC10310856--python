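"""Diffuse GWAS-style seed weights over a planted interactome.

Builds a 10-block synthetic protein-interaction network with seed genes
concentrated in one block, runs Personalized PageRank and selects the top
25% of nodes, then reports how strongly the selection favors the seeded
community.
"""

from glianet import (
    PlantedNetworkSpec,
    make_planted_interactome,
    personalized_pagerank,
    select_top_fraction,
)

spec = PlantedNetworkSpec(rng_seed=11)
graph, block_of, seeds = make_planted_interactome(spec)
print(f"interactome: {graph.number_of_nodes()} genes, {graph.number_of_edges()} interactions")
print(f"seeds: {len(seeds.weights)} genes, total -log10(p) mass {sum(seeds.weights.values()):.1f}")

scores = personalized_pagerank(graph, seeds, damping=0.85)
expansion = select_top_fraction(scores, fraction=0.25)

seeded_block = spec.seed_blocks[0]
in_block = sum(block_of[g] == seeded_block for g in expansion.selected)
print(f"selected top 25%: {len(expansion.selected)} genes")
print(f"  from the seeded community: {in_block} "
      f"(community size {spec.block_size}; random expectation ~{len(expansion.selected)//spec.n_blocks})")
print("top 5 by propagation score:")
for g in expansion.selected[:5]:
    tag = "seed" if g in seeds.weights else f"block {block_of[g]}"
    print(f"  {g}  score {scores[g]:.4f}  ({tag})")
# A selection dominated by the seeded community means the diffusion pulled in
# the interaction partners of the risk genes, which is the point of expansion.
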