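"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- rank correlation -------------------------------------------------------


def midranks(v):
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_oracle(x, y):
    """Spearman rho plus the exact two-sided permutation p over all n! relabelings."""
    rx, ry = midranks(x), midranks(y)
    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


# --- GSEA running sum -------------------------------------------------------


def es_oracle(metric_sorted, member_flags, exponent):
    """Step-by-step running-sum ES on an already-ranked list."""
    N = len(metric_sorted)
    nh = sum(member_flags)
    denom = sum(abs(m) ** exponent for m, f in zip(metric_sorted, member_flags) if f)
    run, best, curve = 0.0, 0.0, []
    for m, f in zip(metric_sorted, member_flags):
        if f:
            run += (abs(m) ** exponent / denom) if denom > 0 else 1.0 / nh
        else:
            run -= 1.0 / (N - nh)
        curve.append(run)
        if abs(run) > abs(best):
            best = run
    return best, curve


def s2n_oracle(x1, x2):
    """Classic signal-to-noise (mu2-mu1)/(sigma2+sigma1), sigmas floored at 0.2|mu|."""
    def stats_(v):
        n = len(v)
        m = sum(v) / n
        var = sum((a - m) ** 2 for a in v) / (n - 1)
        return m, max(math.sqrt(var), 0.2 * abs(m))

    m1, s1 = stats_(x1)
    m2, s2 = stats_(x2)
    if s1 + s2 == 0:
        return 0.0
    return (m2 - m1) / (s2 + s1)


def gsea_exact_phenotype_oracle(X, genes, n1, member_set, exponent):
    """Exact phenotype-permutation GSEA for a tiny cohort.

    X: genes x samples array (first n1 columns = earlier stage). Enumerates
    every relabeling, recomputes the s2n ranking and ES, and returns
    (observed es, exact plus-one p restricted to same-sign relabelings).
    """
    n = X.shape[1]

    def es_for(group2_idx):
        g2 = set(group2_idx)
        metrics = []
        for gi, gene in enumerate(genes):
            x2 = [X[gi, j] for j in range(n) if j in g2]
            x1 = [X[gi, j] for j in range(n) if j not in g2]
            metrics.append(s2n_oracle(x1, x2))
        order = sorted(range(len(genes)), key=lambda i: (-metrics[i], genes[i]))
        ms = [metrics[i] for i in order]
        flags = [genes[i] in member_set for i in order]
        return es_oracle(ms, flags, exponent)[0]

    obs = es_for(range(n1, n))
    perm_es = [es_for(c) for c in itertools.combinations(range(n), n - n1)]
    same = [e for e in perm_es if (e >= 0) == (obs >= 0)]
    extreme = sum(1 for e in same if abs(e) >= abs(obs) - 1e-12)
    return obs, (1 + extreme) / (1 + len(same))


# --- motif scanning ---------------------------------------------------------

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def int_logodds_oracle(matrix, background, pseudocount, granularity=1e-3):
    """Integer-discretized log-odds table, recomputed independently."""
    L = len(matrix)
    table = []
    for i in range(L):
        row = []
        for b in range(4):
            p = (matrix[i][b] + pseudocount * background[b]) / (1.0 + pseudocount)
            row.append(int(round(math.log2(p / background[b]) / granularity)))
        table.append(row)
    return table


def scan_oracle(matrix, background, pseudocount, seq, p_threshold):
    """Hits by scoring every window on both strands, thresholded against the
    null score distribution enumerated exhaustively over all 4^L words."""
    table = int_logodds_oracle(matrix, background, pseudocount)
    L = len(table)
    # exhaustive null: every length-L word, probability = product of background
    scores = np.zeros(1)
    probs = np.ones(1)
    for i in range(L):
        scores = (scores[:, None] + np.array(table[i])[None, :]).ravel()
        probs = (probs[:, None] * np.array(background)[None, :]).ravel()
    obs_p = {}

    def pval(s):
        if s not in obs_p:
            obs_p[s] = float(probs[scores >= s].sum())
        return obs_p[s]

    # reverse-complement table: reversed positions, complemented columns
    rc_table = [list(reversed(row)) for row in reversed(table)]
    hits = []
    for strand, tab in (("+", table), ("-", rc_table)):
        for pos in range(len(seq) - L + 1):
            s = 0
            for i in range(L):
                b = seq[pos + i]
                s += tab[i][_BASE[b]] if b in _BASE else 0
            if pval(s) <= p_threshold:
                hits.append((pos, strand, s))
    return sorted(hits)


# --- OLS and rank test ------------------------------------------------------


def ols_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    beta = sum((a - mx) * (b - my) for a, b in zip(x, y)) / sxx
    return beta, my - beta * mx


def mwu_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    na = len(a)

    def ustat(idx_a):
        aa = [pooled[i] for i in idx_a]
        bb = [pooled[i] for i in range(len(pooled)) if i not in set(idx_a)]
        u = sum(1 for x in aa for y in bb if x > y) + 0.5 * sum(
            1 for x in aa for y in bb if x == y
        )
        return u

    obs = ustat(range(na))
    mu = len(a) * len(b) / 2.0
    count = 0
    total = 0
    for c in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(ustat(c) - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total
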