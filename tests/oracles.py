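"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^2) pairwise loops and exhaustive
threshold scans — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def pairwise_auc(scores, labels) -> float:
    """AUC as the exhaustive all-pairs rank statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def exhaustive_youden(scores, labels):
    """Best threshold by exhaustive scan of "score >= t => positive".

    Candidates are every distinct score plus a +inf sentinel; ties in J are
    broken by higher specificity, then lower threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_key, best = None, None
    for t in [np.inf] + sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        ss = (pred & labels).sum() / n_pos
        sp = 1.0 - (pred & ~labels).sum() / n_neg
        key = (ss + sp - 1.0, sp, -t)
        if best_key is None or key > best_key:
            best_key, best = key, (t, ss, sp)
    return best


def brute_placements(scores, labels):
    """Per-subject placement values by double loop (DeLong components)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]

    def frac(p, q):
        return 1.0 if p > q else (0.5 if p == q else 0.0)

    v10 = np.array([np.mean([frac(p, q) for q in neg]) for p in pos])
    v01 = np.array([np.mean([frac(p, q) for p in pos]) for q in neg])
    return v10, v01


def brute_delong_moments(scores_a, scores_b, labels):
    """Variances/covariance of the paired AUC estimates from brute placements."""
    v10_a, v01_a = brute_placements(scores_a, labels)
    v10_b, v01_b = brute_placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    var_a = v10_a.var(ddof=1) / m + v01_a.var(ddof=1) / n
    var_b = v10_b.var(ddof=1) / m + v01_b.var(ddof=1) / n
    cov = (
        np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
        + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    )
    return var_a, var_b, cov
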