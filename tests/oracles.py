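"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most naive route available
(explicit loops, enumeration, closed forms) and never shares code with the
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def naive_average_ranks(values) -> list[float]:
    """Ranks 1..N ascending with average ties, by counting comparisons."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2)
    return ranks


def naive_es(values, gene_ids, set_genes, alpha: float) -> float:
    """ssGSEA enrichment score by an explicit double loop over the walk."""
    n = len(values)
    ranks = naive_average_ranks(values)
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [gene_ids[i] in set_genes for i in order]
    n_in = sum(in_set)
    assert 0 < n_in < n
    w = [ranks[order[j]] ** alpha if in_set[j] else 0.0 for j in range(n)]
    w_total = sum(w)
    es = 0.0
    for j in range(n):
        p_in = sum(w[: j + 1]) / w_total
        p_out = sum(1 for k in range(j + 1) if not in_set[k]) / (n - n_in)
        es += p_in - p_out
    return es


def logrank_chi2(times, events, groups) -> float:
    """Two-group log-rank chi-square from explicitly tabulated risk sets."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (groups == 0)).sum()
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d_a = (dying & (groups == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def pairwise_auc(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs correctly ordered,
    ties counting one half — the O(n^2) definition."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
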