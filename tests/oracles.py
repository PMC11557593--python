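"""Independent brute-force oracles for the evaluation metrics.

Each function enumerates pairs or thresholds directly from the definitions,
with no shared code with the package implementation; they are only feasible
at small n and serve as the ground truth the fast implementations must match.
"""

from __future__ import annotations

import numpy as np


def auroc_bruteforce(scores, labels) -> float:
    """Pair enumeration of the Mann-Whitney statistic, ties credited 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def auprc_bruteforce(scores, labels) -> float:
    """Average precision by stepping through distinct descending scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int((y[pred] == 1).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def best_f1_bruteforce(scores, labels) -> float:
    """Maximum F1 over every distinct-score threshold (>= rule)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    best = 0.0
    for thr in set(s):
        pred = (s >= thr).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        best = max(best, f1)
    return best


def c_index_bruteforce(risks, times, events) -> float:
    """Harrell's c by full pair enumeration (t_i < t_j, d_i = 1 comparable)."""
    eta = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    num = 0.0
    den = 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j or not (t[i] < t[j] and d[i] == 1):
                continue
            den += 1
            if eta[i] > eta[j]:
                num += 1.0
            elif eta[i] == eta[j]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den
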