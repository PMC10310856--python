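"""Community detection on the expanded subgraph and module significance.

The selected top-fraction subgraph is partitioned with walktrap; communities
larger than ``max_size`` are recursively re-clustered on their induced
subgraph until every community fits or can no longer be split.  Communities
with more than ``min_size`` genes are reported as modules and scored by a
two-sample Kolmogorov-Smirnov test of member propagation scores against the
remaining scored nodes, with Benjamini-Hochberg control across the modules of
one trait.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats
from ._stats import bh_adjust

from .exceptions import GlianetError, ValidationError
from .expansion import PropagationScores, personalized_pagerank, select_top_fraction
from .io import SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "Community",
    "Module",
    "ModuleCatalog",
    "PipelineConfig",
    "iterative_walktrap",
    "ks_module_significance",
    "discover_significant_modules",
]

MAX_RECLUSTER_DEPTH = 20


@dataclass(frozen=True)
class Community:
    """One final community; ``unsplittable`` flags an oversized community
    walktrap could not break apart."""

    genes: frozenset[str]
    unsplittable: bool = False

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Module:
    """A community of > min_size genes with its propagation-score enrichment."""

    genes: frozenset[str]
    trait: str
    ks_statistic: float = float("nan")
    p_raw: float = float("nan")
    p_adjusted: float = float("nan")
    significant: bool = False
    unsplittable: bool = False

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleCatalog:
    """All modules found for one trait's run."""

    trait: str
    modules: list[Module] = field(default_factory=list)

    @property
    def significant_modules(self) -> list[Module]:
        return [m for m in self.modules if m.significant]

    @property
    def all_module_genes(self) -> set[str]:
        """Union of genes across the significant modules."""
        out: set[str] = set()
        for m in self.significant_modules:
            out |= m.genes
        return out


@dataclass
class PipelineConfig:
    """Tunable knobs of the expansion -> clustering -> scoring pipeline.

    Defaults follow the reference workflow: damping 0.85, top 25% selection,
    re-cluster communities above 300 nodes, report modules above 10 genes,
    walktrap walks of length 4, BH-adjusted alpha 0.05.
    """

    damping: float = 0.85
    fraction: float = 0.25
    max_size: int = 300
    min_size: int = 10
    steps: int = 4
    alpha: float = 0.05
    ks_alternative: str = "greater"  # member scores stochastically greater
    background: str = "selected"  # or "all": KS background beyond the subgraph


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def _walktrap_partition(graph: nx.Graph, steps: int) -> list[set[str]]:
    g, nodes = _to_igraph(graph)
    clustering = g.community_walktrap(steps=steps).as_clustering()
    return [{nodes[i] for i in comm} for comm in clustering]


def iterative_walktrap(
    subgraph: nx.Graph,
    max_size: int = 300,
    min_size: int = 10,
    steps: int = 4,
) -> list[Community]:
    """Partition ``subgraph`` with walktrap, re-clustering oversized communities.

    Any community with more than ``max_size`` nodes is re-clustered on its
    induced subgraph, recursively, until all communities fit or one refuses to
    split (it is then kept with ``unsplittable=True`` and a warning).
    Communities of ``min_size`` or fewer nodes are discarded from the result.
    Returns an empty list for an empty graph.
    """
    if max_size <= min_size:
        raise ValidationError(f"max_size ({max_size}) must exceed min_size ({min_size})")
    if subgraph.number_of_nodes() == 0:
        return []

    final: list[Community] = []

    def recurse(g: nx.Graph, depth: int) -> None:
        if depth > MAX_RECLUSTER_DEPTH:
            raise GlianetError(
                f"re-clustering exceeded depth {MAX_RECLUSTER_DEPTH} "
                f"on a community of {g.number_of_nodes()} nodes"
            )
        parts = _walktrap_partition(g, steps)
        for part in parts:
            if len(part) <= max_size:
                final.append(Community(frozenset(part)))
            elif len(parts) == 1:
                warnings.warn(
                    f"community of {len(part)} nodes could not be split below "
                    f"{max_size}; kept as-is",
                    stacklevel=2,
                )
                final.append(Community(frozenset(part), unsplittable=True))
            else:
                recurse(g.subgraph(part).copy(), depth + 1)

    recurse(subgraph, 0)
    return [c for c in final if len(c) > min_size]


def ks_module_significance(
    modules: list[Community] | list[frozenset[str]] | list[set[str]],
    scores: PropagationScores,
    alpha: float = 0.05,
    alternative: str = "greater",
    trait: str | None = None,
) -> list[Module]:
    """Score each module's propagation-score enrichment over the background.

    Per module, a two-sample KS test compares member scores with the scores of
    every other scored node; ``alternative="greater"`` tests whether member
    scores are stochastically greater (the enrichment direction),
    ``"two-sided"`` is available.  Raw p-values are Benjamini-Hochberg
    adjusted across all modules of the run and flagged at ``alpha``.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"alternative must be 'greater' or 'two-sided', got {alternative}")
    trait = trait if trait is not None else scores.seed_trait
    communities = [m if isinstance(m, Community) else Community(frozenset(m)) for m in modules]
    all_nodes = set(scores.scores)
    out: list[Module] = []
    for comm in communities:
        members = comm.genes
        missing = members - all_nodes
        if missing:
            raise ValidationError(f"module genes without a score: {sorted(missing)[:5]}")
        background = all_nodes - members
        if not background:
            raise ValidationError("module spans the entire scored node set; no background")
        mem = np.array([scores.scores[g] for g in sorted(members)])
        bg = np.array([scores.scores[g] for g in sorted(background)])
        # scipy's 'less' alternative = CDF(members) below CDF(background),
        # i.e. member scores stochastically GREATER.
        scipy_alt = "less" if alternative == "greater" else "two-sided"
        res = stats.ks_2samp(mem, bg, alternative=scipy_alt)
        out.append(
            Module(
                genes=members,
                trait=trait,
                ks_statistic=float(res.statistic),
                p_raw=float(res.pvalue),
                unsplittable=comm.unsplittable,
            )
        )
    if out:
        reject, p_adj = bh_adjust([m.p_raw for m in out], alpha=alpha)
        for m, r, p in zip(out, reject, p_adj):
            m.p_adjusted = float(p)
            m.significant = bool(r)
    return out


def discover_significant_modules(
    net: nx.Graph,
    seeds: SeedSet,
    config: PipelineConfig | None = None,
) -> ModuleCatalog:
    """Run the full expansion pipeline for one trait.

    Seed weights are diffused by Personalized PageRank, the top-``fraction``
    nodes are selected, their induced subgraph is clustered by iterative
    walktrap, and each module is KS-scored against the background chosen in
    the config (the selected subgraph by default, the whole interactome with
    ``background="all"``).
    """
    cfg = config or PipelineConfig()
    scores = personalized_pagerank(net, seeds, damping=cfg.damping)
    expansion = select_top_fraction(scores, cfg.fraction)
    induced = net.subgraph(expansion.selected).copy()
    communities = iterative_walktrap(induced, cfg.max_size, cfg.min_size, cfg.steps)
    if cfg.background == "selected":
        pool = {n: scores.scores[n] for n in expansion.selected}
        total = sum(pool.values())
        bg_scores = PropagationScores(
            {n: v / total for n, v in pool.items()}, cfg.damping, seeds.trait
        )
    elif cfg.background == "all":
        bg_scores = scores
    else:
        raise ValidationError(f"background must be 'selected' or 'all', got {cfg.background}")
    mods = ks_module_significance(
        communities, bg_scores, alpha=cfg.alpha, alternative=cfg.ks_alternative, trait=seeds.trait
    )
    if not mods:
        logger.warning("trait %s: no community exceeded %d genes", seeds.trait, cfg.min_size)
    return ModuleCatalog(trait=seeds.trait, modules=mods)
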