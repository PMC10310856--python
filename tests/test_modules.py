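import itertools

import networkx as nx
import numpy as np
import pytest

from glianet import (
    Community,
    EmptyResultError,
    PipelineConfig,
    PropagationScores,
    SeedSet,
    ValidationError,
    discover_significant_modules,
    iterative_walktrap,
    ks_module_significance,
    make_planted_interactome,
    PlantedNetworkSpec,
)


def exact_one_sided_ks_p(members, background):
    """Exhaustive permutation oracle for the one-sided two-sample KS test."""
    pool = list(members) + list(background)
    n = len(members)

    def d_plus(mem, bg):
        xs = sorted(set(pool))
        return max(
            np.mean([v <= x for v in bg]) - np.mean([v <= x for v in mem]) for x in xs
        )

    observed = d_plus(members, background)
    hits = total = 0
    for comb in itertools.combinations(range(len(pool)), n):
        mem = [pool[i] for i in comb]
        bg = [pool[i] for i in range(len(pool)) if i not in comb]
        total += 1
        hits += d_plus(mem, bg) >= observed - 1e-12
    return hits / total


def make_scores(mapping):
    total = sum(mapping.values())
    return PropagationScores({k: v / total for k, v in mapping.items()}, 0.85, "t")


class TestIterativeWalktrap:
    def test_two_cliques_split_into_two_communities(self, two_clique_graph):
        comms = iterative_walktrap(two_clique_graph, max_size=300, min_size=10)
        assert sorted(len(c) for c in comms) == [20, 20]
        genes = [c.genes for c in comms]
        assert {g[0] for g in map(sorted, genes)} == {"L00", "R00"}

    def test_small_communities_discarded(self):
        g = nx.compose(
            nx.relabel_nodes(nx.complete_graph(8), {i: f"S{i}" for i in range(8)}),
            nx.relabel_nodes(nx.complete_graph(15), {i: f"B{i:02d}" for i in range(15)}),
        )
        g.add_edge("S0", "B00")
        comms = iterative_walktrap(g, max_size=300, min_size=10)
        assert [len(c) for c in comms] == [15]

    def test_oversized_communities_recursively_reclustered(self):
        spec = PlantedNetworkSpec(n_blocks=4, block_size=120, p_in=0.15, p_out=0.005, rng_seed=3)
        g, labels, _ = make_planted_interactome(spec)
        comms = iterative_walktrap(g, max_size=100, min_size=10)
        assert all(len(c) <= 100 or c.unsplittable for c in comms)

    def test_partition_property_before_min_size_discard(self):
        spec = PlantedNetworkSpec(rng_seed=11)
        g, _, _ = make_planted_interactome(spec)
        comms = iterative_walktrap(g, max_size=300, min_size=0)
        all_genes = [gene for c in comms for gene in c.genes]
        assert len(all_genes) == len(set(all_genes)) == g.number_of_nodes()

    def test_planted_blocks_recovered_with_high_ari(self):
        pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        spec = PlantedNetworkSpec(n_blocks=5, block_size=100, p_in=0.2, p_out=0.01, rng_seed=5)
        g, labels, _ = make_planted_interactome(spec)
        comms = iterative_walktrap(g, max_size=300, min_size=10)
        assert all(len(c) <= 300 for c in comms)
        pred = {n: i for i, c in enumerate(comms) for n in c.genes}
        nodes = sorted(pred)
        ari = adjusted_rand_score([labels[n] for n in nodes], [pred[n] for n in nodes])
        assert ari >= 0.9

    def test_empty_graph_gives_empty_list(self):
        assert iterative_walktrap(nx.Graph(), 300, 10) == []

    def test_unsplittable_clique_kept_with_warning(self):
        g = nx.relabel_nodes(nx.complete_graph(30), {i: f"K{i:02d}" for i in range(30)})
        with pytest.warns(UserWarning, match="could not be split"):
            comms = iterative_walktrap(g, max_size=20, min_size=5)
        assert len(comms) == 1 and comms[0].unsplittable

    def test_bad_size_thresholds_rejected(self, two_clique_graph):
        with pytest.raises(ValidationError):
            iterative_walktrap(two_clique_graph, max_size=10, min_size=10)


class TestKsModuleSignificance:
    def test_identical_distribution_not_significant(self):
        scores = make_scores({f"N{i:02d}": 1.0 for i in range(20)})
        mods = ks_module_significance([{f"N{i:02d}" for i in range(5)}], scores)
        assert mods[0].ks_statistic == 0.0
        assert mods[0].p_raw == 1.0
        assert not mods[0].significant

    def test_perfect_separation_matches_permutation_oracle(self):
        scores = make_scores(
            {"A": 0.9, "B": 0.8, "C": 0.7, "X": 0.1, "Y": 0.2, "Z": 0.3}
        )
        mods = ks_module_significance([{"A", "B", "C"}], scores)
        assert mods[0].ks_statistic == pytest.approx(1.0)
        oracle = exact_one_sided_ks_p([0.9, 0.8, 0.7], [0.1, 0.2, 0.3])
        assert oracle == pytest.approx(0.05)
        assert mods[0].p_raw == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("perm_seed", [0, 1])
    def test_matches_permutation_oracle_on_random_splits(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        vals = rng.uniform(0.1, 1, 9)
        names = [f"N{i}" for i in range(9)]
        scores = make_scores(dict(zip(names, vals)))
        member = set(names[:4])
        mods = ks_module_significance([member], scores)
        oracle = exact_one_sided_ks_p(vals[:4].tolist(), vals[4:].tolist())
        assert mods[0].p_raw == pytest.approx(oracle, rel=1e-9)

    def test_bh_adjustment_step_up(self):
        # three modules engineered to produce the ordered raw p's, then
        # checked against the hand-computed step-up adjustment
        scores = make_scores({f"N{i:02d}": float(i + 1) for i in range(40)})
        top = sorted(scores.scores, key=scores.scores.get, reverse=True)
        mods = ks_module_significance([set(top[:12]), set(top[:8]), set(top[20:26])], scores)
        raw = np.array([m.p_raw for m in mods])
        m = len(raw)
        order = np.argsort(raw)
        stepup = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, raw[i] * m / (rank_idx + 1))
            stepup[i] = running
        assert [mod.p_adjusted for mod in mods] == pytest.approx(stepup.tolist())
        for mod in mods:
            assert mod.p_adjusted >= mod.p_raw
            assert mod.significant == (mod.p_adjusted < 0.05)

    def test_module_covering_everything_rejected(self):
        scores = make_scores({"A": 1.0, "B": 2.0})
        with pytest.raises(ValidationError):
            ks_module_significance([{"A", "B"}], scores)

    def test_unscored_module_gene_rejected(self):
        scores = make_scores({"A": 1.0, "B": 2.0})
        with pytest.raises(ValidationError):
            ks_module_significance([{"A", "Q"}], scores)


class TestDiscoverSignificantModules:
    def test_planted_block_found_significant(self):
        g, labels, seeds = make_planted_interactome(PlantedNetworkSpec(rng_seed=42))
        catalog = discover_significant_modules(g, seeds, PipelineConfig())
        block0 = {n for n, b in labels.items() if b == 0}
        pure = [
            m
            for m in catalog.significant_modules
            if len(m.genes & block0) / len(m.genes) >= 0.8
        ]
        assert pure, "the seeded block should surface as a significant module"

    def test_catalog_modules_disjoint(self):
        g, _, seeds = make_planted_interactome(PlantedNetworkSpec(rng_seed=13))
        catalog = discover_significant_modules(g, seeds)
        seen = set()
        for m in catalog.modules:
            assert not (m.genes & seen)
            seen |= m.genes

    def test_no_seed_overlap_is_error(self):
        g, _, _ = make_planted_interactome(PlantedNetworkSpec(rng_seed=1))
        with pytest.raises(EmptyResultError):
            discover_significant_modules(g, SeedSet("t", {"NOPE": 1.0}))
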