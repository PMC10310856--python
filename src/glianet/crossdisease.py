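"""Cross-disease module overlap, shared-module grouping and Fisher enrichment.

Disease-level similarity is the Jaccard index between the unions of
significant-module genes of two traits.  Individual modules of different
traits are linked when their gene sets overlap at Jaccard >= threshold
(0.7 by default); connected components of that link graph spanning at least
two traits form shared-module groups.  Gene-set enrichment of any gene list
uses the one-sided Fisher exact test with Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from ._stats import bh_adjust

from .exceptions import EmptyResultError, ValidationError
from .modules import ModuleCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleGroup",
    "jaccard_index",
    "disease_similarity_matrix",
    "group_shared_modules",
    "fisher_enrichment",
    "read_gmt",
]


@dataclass
class ModuleGroup:
    """Modules of >= 2 traits chained together by strong pairwise overlap."""

    members: list[tuple[str, int]]  # (trait, module index in its catalog)
    traits_covered: set[str]
    union_genes: set[str]


def jaccard_index(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; raises if both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValidationError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def disease_similarity_matrix(catalogs: Sequence[ModuleCatalog]) -> pd.DataFrame:
    """Pairwise Jaccard between traits' significant-module gene unions.

    A trait with no significant modules contributes zero rows/columns (with a
    warning); its diagonal entry is 0 rather than 1 since its gene set is
    empty.
    """
    if len(catalogs) < 2:
        raise ValidationError("need at least two catalogs")
    traits = [c.trait for c in catalogs]
    unions = [c.all_module_genes for c in catalogs]
    for t, u in zip(traits, unions):
        if not u:
            logger.warning("trait %s has no significant modules; similarity row is 0", t)
    n = len(catalogs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if unions[i] or unions[j]:
                mat[i, j] = mat[j, i] = jaccard_index(unions[i], unions[j])
    return pd.DataFrame(mat, index=traits, columns=traits)


def group_shared_modules(
    catalogs: Sequence[ModuleCatalog],
    threshold: float = 0.7,
) -> list[ModuleGroup]:
    """Group significant modules shared across at least two traits.

    Builds a graph whose nodes are significant modules and whose edges link
    modules of *different* traits with Jaccard >= threshold, then returns the
    connected components that span >= 2 traits (single-link closure).
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    nodes: list[tuple[str, int]] = []
    genes: dict[tuple[str, int], frozenset[str]] = {}
    for cat in catalogs:
        for i, m in enumerate(cat.modules):
            if m.significant:
                key = (cat.trait, i)
                nodes.append(key)
                genes[key] = m.genes
    link = nx.Graph()
    link.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if u[0] == v[0]:
                continue  # within-trait pairs never form edges
            if genes[u] and genes[v] and jaccard_index(genes[u], genes[v]) >= threshold:
                link.add_edge(u, v)
    groups = []
    for comp in nx.connected_components(link):
        traits = {t for t, _ in comp}
        if len(traits) >= 2:
            union: set[str] = set()
            for key in comp:
                union |= genes[key]
            groups.append(
                ModuleGroup(members=sorted(comp), traits_covered=traits, union_genes=union)
            )
    groups.sort(key=lambda g: g.members)
    return groups


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term <TAB> description <TAB> gene..."""
    annotation: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            annotation[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    if not annotation:
        raise ValidationError(f"{path}: no gene sets found")
    return annotation


def fisher_enrichment(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact enrichment with BH control.

    For each term with K background hits, the 2x2 table of a query of size n
    drawn from a background of size N with k hits is tested for
    over-representation; terms with zero background hits are skipped.  Returns
    a DataFrame sorted by adjusted p with columns
    term, k, K, n, N, p_raw, p_adjusted.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise EmptyResultError("empty query gene set")
    if not query <= background:
        raise ValidationError(
            f"query must be a subset of the background; {len(query - background)} genes outside"
        )
    N, n = len(background), len(query)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        _, p = stats.fisher_exact([[k, n - k], [K - k, N - n - K + k]], alternative="greater")
        rows.append((term, k, K, n, N, float(p)))
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p_raw", "p_adjusted"])
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    _, p_adj = bh_adjust(df["p_raw"], alpha=alpha)
    df["p_adjusted"] = p_adj
    return df.sort_values(["p_adjusted", "p_raw", "term"]).reset_index(drop=True)
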