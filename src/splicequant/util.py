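"""Small shared numerics."""

from __future__ import annotations

import numpy as np
from scipy import stats


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both positive and negative labels")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
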