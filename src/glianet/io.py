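"""Parsing and validation of interaction edge tables and GWAS-style seed tables.

Edge tables are TSV files with a header line and columns ``gene_a``,
``gene_b`` and optionally ``score`` (a confidence in [0, 1], e.g. a STRING
combined score rescaled to [0, 1]); lines starting with ``#`` are ignored.
Seed tables are TSV with columns ``trait``, ``gene``, ``pvalue``.

Gene identifiers are treated as opaque strings: they are upper-cased and
whitespace-stripped, but no identifier mapping service is consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "read_edge_table",
    "build_interactome",
    "write_edge_table",
    "load_seed_weights",
    "read_association_table",
    "write_seed_table",
]


@dataclass
class SeedSet:
    """Per-trait starting weights for network propagation.

    ``weights`` maps gene identifiers to non-negative weights; for GWAS input
    the weight is -log10(p) of the strongest association of the gene with the
    trait.
    """

    trait: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: w for g, w in self.weights.items() if not np.isfinite(w) or w < 0}
        if bad:
            raise ValidationError(f"seed weights must be finite and >= 0, got {bad}")

    def __len__(self) -> int:
        return len(self.weights)

    def genes(self) -> set[str]:
        return set(self.weights)


def _canon(gene: str) -> str:
    return str(gene).strip().upper()


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read one TSV edge table into a DataFrame with canonicalized identifiers.

    Raises :class:`ValidationError` naming the offending row (1-based data row
    number, comments excluded) on missing identifiers or out-of-range scores.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "gene_a" not in cols or "gene_b" not in cols:
        raise ValidationError(f"{path}: edge table needs gene_a/gene_b columns, got {cols}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        a, b = getattr(row, "gene_a"), getattr(row, "gene_b")
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            raise ValidationError(f"{path}: malformed row {i}: missing gene identifier")
    df["gene_a"] = df["gene_a"].map(_canon)
    df["gene_b"] = df["gene_b"].map(_canon)
    if "score" in df.columns:
        raw = df["score"]
        score = pd.to_numeric(raw, errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = df.index[(score.isna() & ~blank) | (score < 0) | (score > 1)]
        if len(bad):
            raise ValidationError(
                f"{path}: malformed row {bad[0] + 1}: score must be a number in [0, 1]"
            )
        df["score"] = score  # blank scores stay NaN: the edge passes any filter
    return df


def build_interactome(
    edge_tables: Sequence[pd.DataFrame | str | Path],
    score_threshold: float = 0.75,
) -> nx.Graph:
    """Merge edge tables into one simple undirected graph.

    Tables carrying a ``score`` column are filtered with a strict inequality
    (``score > score_threshold``); scoreless tables contribute all of their
    edges.  Self-loops are dropped, duplicated edges (in either orientation)
    are collapsed keeping the maximum score before thresholding, and the
    resulting graph is simple and undirected.

    Parameters
    ----------
    edge_tables:
        DataFrames from :func:`read_edge_table`, or paths to TSV files.
    score_threshold:
        Confidence cutoff in [0, 1]; edges with score <= threshold are removed.
    """
    if not 0 <= score_threshold <= 1:
        raise ValidationError(f"score_threshold must be in [0, 1], got {score_threshold}")
    # (a, b) lexicographic -> best score (or None for scoreless tables)
    best: dict[tuple[str, str], float | None] = {}
    for tbl in edge_tables:
        df = read_edge_table(tbl) if isinstance(tbl, (str, Path)) else tbl
        has_score = "score" in df.columns
        for row in df.itertuples(index=False):
            a, b = _canon(row.gene_a), _canon(row.gene_b)
            if a == b:
                continue  # self-loop
            key = (a, b) if a < b else (b, a)
            s = float(getattr(row, "score")) if has_score else None
            if s is not None and np.isnan(s):
                s = None
            if key in best:
                prev = best[key]
                # a scoreless observation always passes -> treat as max
                if prev is None or s is None:
                    best[key] = None
                else:
                    best[key] = max(prev, s)
            else:
                best[key] = s
    graph = nx.Graph()
    for (a, b), s in best.items():
        if s is None or s > score_threshold:
            graph.add_edge(a, b, **({} if s is None else {"score": s}))
    if graph.number_of_edges() == 0:
        raise EmptyResultError("no edges survive filtering; interactome is empty")
    logger.info(
        "interactome: %d nodes, %d edges (threshold %.3g)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        score_threshold,
    )
    return graph


def write_edge_table(graph: nx.Graph, path: str | Path) -> None:
    """Dump a graph to the canonical TSV edge format (round-trips through
    :func:`build_interactome`)."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data.get("score", "")))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s}\n")


def read_association_table(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-style TSV with trait / gene / pvalue columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"trait", "gene", "pvalue"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: association table needs columns {sorted(required)}")
    return df


def load_seed_weights(
    association_table: pd.DataFrame | str | Path,
    traits_to_pool: Iterable[str],
    trait_label: str | None = None,
) -> SeedSet:
    """Build a :class:`SeedSet` from an association table.

    Rows of all pooled traits are combined; when a gene appears several times
    (within or across pooled traits) the highest -log10(p) is kept.  P-values
    must lie in (0, 1]; p = 1 yields weight 0 and is retained.
    """
    df = (
        read_association_table(association_table)
        if isinstance(association_table, (str, Path))
        else association_table.copy()
    )
    traits = list(traits_to_pool)
    if not traits:
        raise ValidationError("traits_to_pool must name at least one trait")
    df = df[df["trait"].isin(traits)]
    if df.empty:
        raise EmptyResultError(f"no association rows for traits {traits}")
    pvals = pd.to_numeric(df["pvalue"], errors="coerce")
    if pvals.isna().any() or (pvals <= 0).any() or (pvals > 1).any():
        raise ValidationError("p-values must be numbers in (0, 1]")
    weights: dict[str, float] = {}
    for gene, p in zip(df["gene"].map(_canon), pvals):
        w = -np.log10(p)
        weights[gene] = max(weights.get(gene, 0.0), w)
    label = trait_label if trait_label is not None else "+".join(traits)
    return SeedSet(trait=label, weights=weights)


def write_seed_table(seeds: SeedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tweight\ttrait\n")
        for g in sorted(seeds.weights):
            fh.write(f"{g}\t{seeds.weights[g]:.10g}\t{seeds.trait}\n")
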