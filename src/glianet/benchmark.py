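"""Gold-standard construction and ROC benchmarking of propagation scores.

Positives can be taken from a disease-association score table (genes above
the third quartile, or the genes attaining the maximum association score) or
supplied directly as a curated list such as drug targets.  Ranking quality is
the area under the ROC curve, computed by the Mann-Whitney pair-counting
identity with ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import EmptyResultError, ValidationError
from .expansion import PropagationScores

logger = logging.getLogger(__name__)

__all__ = ["GoldStandard", "RocResult", "split_gold_standard", "roc_auc"]


@dataclass
class GoldStandard:
    """A labelled positive gene set (above_Q3 / max_score / drug_target)."""

    label: str
    positives: set[str]

    def __post_init__(self) -> None:
        if self.label == "above_Q3" and not self.positives:
            # degenerate all-equal input; warned by split_gold_standard
            return
        if not self.positives:
            raise ValidationError(f"gold standard '{self.label}' has no positives")


@dataclass
class RocResult:
    auc: float
    curve: list[tuple[float, float]] = field(repr=False)  # (FPR, TPR)
    n_pos: int = 0
    n_neg: int = 0


def split_gold_standard(
    association_scores: Mapping[str, float],
) -> tuple[GoldStandard, GoldStandard]:
    """Split association scores into the above-Q3 and maximum-score positives.

    Q3 is the type-7 (linear interpolation) 75% quantile; the above-Q3 set
    keeps genes with score strictly above it.  When all scores are equal the
    above-Q3 set is empty (warned) and the max set contains every gene.
    """
    if not association_scores:
        raise EmptyResultError("empty association score map")
    genes = np.array(sorted(association_scores))
    vals = np.array([association_scores[g] for g in genes], dtype=float)
    q3 = float(np.quantile(vals, 0.75))  # type-7 linear interpolation
    above = {g for g, v in zip(genes, vals) if v > q3}
    if not above:
        logger.warning("all association scores equal; above-Q3 gold standard is empty")
    mx = vals.max()
    max_set = {g for g, v in zip(genes, vals) if v == mx}
    return GoldStandard("above_Q3", above), GoldStandard("max_score", max_set)


def roc_auc(scores: PropagationScores | Mapping[str, float], gold: GoldStandard) -> RocResult:
    """AUC of the score ranking against the gold standard.

    Negatives are every scored gene not in the positive set.  The AUC is the
    Mann-Whitney statistic (fraction of positive/negative pairs ranked
    correctly, ties 0.5); the returned curve is the stepwise ROC whose
    trapezoidal area equals the AUC.
    """
    score_map = scores.scores if isinstance(scores, PropagationScores) else dict(scores)
    pos = set(gold.positives) & set(score_map)
    if not pos:
        raise EmptyResultError("no gold-standard positive overlaps the scored universe")
    neg = set(score_map) - pos
    if not neg:
        raise ValidationError("every scored gene is a positive; no negatives to rank against")
    y = np.array([g in pos for g in score_map])
    s = np.fromiter(score_map.values(), float, len(score_map))
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties as 0.5 wins
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # stepwise ROC: sweep thresholds from high to low, grouping tied scores
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    return RocResult(auc=float(auc), curve=curve, n_pos=n_pos, n_neg=n_neg)
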