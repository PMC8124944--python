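"""Small statistical primitives shared across modules."""

from __future__ import annotations

import numpy as np


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    new_group = np.empty(len(x), dtype=bool)
    new_group[0] = True
    np.not_equal(xs[1:], xs[:-1], out=new_group[1:])
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    ends = np.cumsum(counts)
    avg = ends - (counts - 1) / 2.0  # midrank of each tie group
    ranks = np.empty(len(x))
    ranks[order] = avg[group]
    return ranks


def rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 * P(tie), via the rank statistic."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = average_ranks(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """ROC operating points at every distinct threshold (positive: score >= t).

    Returns an array of rows (threshold, fpr, tpr) ordered from the most
    permissive threshold (-inf) to the strictest (+inf).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    thresholds = candidate_thresholds(scores)
    n_pos = positive.sum()
    n_neg = positive.size - n_pos
    rows = []
    for t in thresholds:
        called = scores >= t
        tpr = (called & positive).sum() / n_pos
        fpr = (called & ~positive).sum() / n_neg
        rows.append((t, fpr, tpr))
    return np.array(rows)


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus -inf/+inf extremes."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def jonckheere_statistic(values: np.ndarray, groups: np.ndarray) -> float:
    """Jonckheere-Terpstra ordered-alternative statistic.

    Sum over ordered group pairs (i < j) of the Mann-Whitney count
    #(x_j > x_i) + 0.5 * #(x_j == x_i).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 ordered groups")
    stat = 0.0
    by_level = [values[groups == g] for g in levels]
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = by_level[i], by_level[j]
            gt = (b[:, None] > a[None, :]).sum()
            eq = (b[:, None] == a[None, :]).sum()
            stat += gt + 0.5 * eq
    return float(stat)
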