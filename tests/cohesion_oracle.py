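"""Independent brute-force cohesion implementation used as a test oracle.

Deliberately naive: explicit Python loops for every correlation, the null
model, connectedness and the per-sample sums. Shares only the documented
null-shuffle protocol with the library (one ``rng.permutation`` per taxon per
iteration, taxa in row order, from ``np.random.default_rng(seed)``); all
arithmetic paths are independent of the library's vectorized code.
"""

import math

import numpy as np


def _pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def brute_force_cohesion(counts, n_null, seed):
    """Return (conn_pos, conn_neg, c_pos, c_neg, npc) arrays for a taxon ×
    sample count matrix."""
    counts = np.asarray(counts, dtype=float)
    n_taxa, n_samples = counts.shape
    rel = np.empty_like(counts)
    for i in range(n_samples):
        col_sum = sum(counts[j, i] for j in range(n_taxa))
        for j in range(n_taxa):
            rel[j, i] = counts[j, i] / col_sum

    obs = [[_pearson(rel[a], rel[b]) for b in range(n_taxa)] for a in range(n_taxa)]

    rng = np.random.default_rng(seed)
    null_total = [[0.0] * n_taxa for _ in range(n_taxa)]
    for _ in range(n_null):
        shuffled = []
        for j in range(n_taxa):
            perm = rng.permutation(n_samples)
            shuffled.append([rel[j, k] for k in perm])
        for a in range(n_taxa):
            for b in range(n_taxa):
                null_total[a][b] += _pearson(shuffled[a], shuffled[b])

    conn_pos = [0.0] * n_taxa
    conn_neg = [0.0] * n_taxa
    for a in range(n_taxa):
        pos, neg = [], []
        for b in range(n_taxa):
            if a == b:
                continue
            corrected = obs[a][b] - null_total[a][b] / n_null
            if math.isnan(corrected):
                continue
            if corrected > 0:
                pos.append(corrected)
            elif corrected < 0:
                neg.append(corrected)
        if pos:
            conn_pos[a] = sum(pos) / len(pos)
        if neg:
            conn_neg[a] = sum(neg) / len(neg)

    c_pos, c_neg, npc = [], [], []
    for i in range(n_samples):
        cp = sum(rel[j, i] * conn_pos[j] for j in range(n_taxa))
        cn = sum(rel[j, i] * conn_neg[j] for j in range(n_taxa))
        c_pos.append(cp)
        c_neg.append(cn)
        npc.append(abs(cn) / cp if cp > 0 else float("nan"))
    return (
        np.array(conn_pos),
        np.array(conn_neg),
        np.array(c_pos),
        np.array(c_neg),
        np.array(npc),
    )
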