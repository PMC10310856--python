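"""Multi-omics integration: Significance A outliers, triple overlap, candidates.

Protein log2 ratios are scored with the Significance A statistic: an
asymmetric robust z built from the 15.87th, 50th and 84.13th percentiles of
the ratio distribution (each flank of a Gaussian is one such percentile
spread wide), with the one-tailed normal p = erfc(z / sqrt 2) / 2.  The three
network expansions (GWAS, transcriptome, proteome) are intersected to the
triple-overlap gene set, from which candidates with sign-concordant and
significant changes in both expression layers are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import erfc

from .exceptions import ValidationError
from .modules import ModuleCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "TripleOverlap",
    "significance_a",
    "read_omics_table",
    "integrate_expansions",
    "select_concordant_candidates",
]


@dataclass
class TripleOverlap:
    """Gene-set overlaps between the three expanded layers."""

    gwas_genes: set[str]
    transcriptome_genes: set[str]
    proteome_genes: set[str]
    pairwise_counts: dict[str, int] = field(init=False)
    triple_genes: set[str] = field(init=False)

    def __post_init__(self) -> None:
        g, t, p = self.gwas_genes, self.transcriptome_genes, self.proteome_genes
        self.pairwise_counts = {
            "gwas∩transcriptome": len(g & t),
            "gwas∩proteome": len(g & p),
            "transcriptome∩proteome": len(t & p),
        }
        self.triple_genes = g & t & p


def significance_a(ratios: Mapping[str, float]) -> pd.DataFrame:
    """Outlier p-value for each (averaged) log ratio.

    With r0 the median and r1 / r-1 the 84.13th / 15.87th percentiles,

        z = (r - r0) / (r1 - r0)   for r > r0
        z = (r0 - r) / (r0 - r-1)  for r < r0,  z = 0 at the median

    and p = erfc(z / sqrt 2) / 2, the upper tail of the standard normal.
    Requires at least 8 finite ratios and non-degenerate percentile spreads.
    Returns a DataFrame with columns gene, ratio, z, p sorted by p.
    """
    genes = sorted(ratios)
    vals = np.array([ratios[g] for g in genes], dtype=float)
    if len(vals) < 8:
        raise ValidationError(f"need >= 8 ratios for stable percentiles, got {len(vals)}")
    if not np.isfinite(vals).all():
        raise ValidationError("ratios must be finite")
    r_lo, r0, r_hi = np.percentile(vals, [15.87, 50.0, 84.13])
    if r_hi <= r0 or r0 <= r_lo:
        raise ValidationError(
            f"degenerate ratio spread (percentiles {r_lo:.4g}, {r0:.4g}, {r_hi:.4g})"
        )
    z = np.where(vals >= r0, (vals - r0) / (r_hi - r0), (r0 - vals) / (r0 - r_lo))
    p = 0.5 * erfc(z / np.sqrt(2.0))
    df = pd.DataFrame({"gene": genes, "ratio": vals, "z": z, "p": p})
    return df.sort_values(["p", "gene"]).reset_index(drop=True)


def read_omics_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene, layer, log2_ratio, pvalue."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "layer", "log2_ratio", "pvalue"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: omics table needs columns {sorted(required)}")
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    return df


def _union_genes(cat: ModuleCatalog, label: str) -> set[str]:
    genes = cat.all_module_genes
    if not genes:
        logger.warning("%s catalog has no significant-module genes", label)
    return genes


def integrate_expansions(
    gwas_cat: ModuleCatalog,
    tx_cat: ModuleCatalog,
    prot_cat: ModuleCatalog,
) -> TripleOverlap:
    """Intersect the significant-module gene unions of the three expansions."""
    return TripleOverlap(
        gwas_genes=_union_genes(gwas_cat, "GWAS"),
        transcriptome_genes=_union_genes(tx_cat, "transcriptome"),
        proteome_genes=_union_genes(prot_cat, "proteome"),
    )


def select_concordant_candidates(
    triple: TripleOverlap | set[str],
    tx: pd.DataFrame,
    prot: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pick triple-overlap genes changing concordantly in both omics layers.

    A candidate must have a transcript record and a protein record, both with
    p < alpha, and log2 ratios of the same sign; the shared direction is
    recorded.  Genes missing a layer record are excluded with a warning.
    Returns a DataFrame with columns gene, log2_transcript, log2_protein,
    direction, sorted by gene.
    """
    genes = triple.triple_genes if isinstance(triple, TripleOverlap) else set(triple)
    tx_map = {r.gene: r for r in tx.itertuples(index=False)}
    prot_map = {r.gene: r for r in prot.itertuples(index=False)}
    rows = []
    missing = []
    for g in sorted(genes):
        if g not in tx_map or g not in prot_map:
            missing.append(g)
            continue
        t, p = tx_map[g], prot_map[g]
        if t.pvalue >= alpha or p.pvalue >= alpha:
            continue
        if np.sign(t.log2_ratio) != np.sign(p.log2_ratio) or t.log2_ratio == 0:
            continue
        rows.append((g, float(t.log2_ratio), float(p.log2_ratio),
                     "up" if t.log2_ratio > 0 else "down"))
    if missing:
        logger.warning(
            "%d triple-overlap genes lack an omics record and were excluded (e.g. %s)",
            len(missing), missing[:5],
        )
    return pd.DataFrame(rows, columns=["gene", "log2_transcript", "log2_protein", "direction"])
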