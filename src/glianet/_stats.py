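"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_raw, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (reject, p_adjusted) for the family of raw p-values.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return np.zeros(0, dtype=bool), p_raw
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return reject, p_adj
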