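"""Naive brute-force oracles: direct double-loop enumerations, kept
deliberately independent of the package's blocked/streamed kernels."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def naive_ranks(values):
    """Ascending midranks by explicit position averaging over a sort."""
    v = list(values)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return np.array(ranks)


def naive_consistency(ff, ffpe, gene_ids, fraction):
    """(k, n, ties, n_excluded) by enumerating every pair explicitly."""
    ff = np.asarray(ff, float)
    ffpe = np.asarray(ffpe, float)
    n_genes = ff.size
    ranks = naive_ranks(ff)
    pairs = list(combinations(range(n_genes), 2))
    n_excl = int(math.floor(fraction * len(pairs) + 1e-9))

    def sort_key(p):
        i, j = p
        a, b = sorted((gene_ids[i], gene_ids[j]))
        return (abs(ranks[i] - ranks[j]), a, b)

    excluded = set(sorted(pairs, key=sort_key)[:n_excl])
    k = n = ties = 0
    for i, j in pairs:
        if (i, j) in excluded:
            continue
        dff = ff[i] - ff[j]
        dfp = ffpe[i] - ffpe[j]
        if dff == 0 or dfp == 0:
            ties += 1
            continue
        n += 1
        if (dff > 0) == (dfp > 0):
            k += 1
    return k, n, ties, n_excl


def naive_stable_pairs(x, gene_ids, threshold):
    """{(gene_i, gene_j): (direction, support)} by per-pair counting."""
    x = np.asarray(x, float)
    n, s = x.shape
    out = {}
    for i, j in combinations(range(n), 2):
        gt = int((x[i] > x[j]).sum())
        lt = int((x[i] < x[j]).sum())
        frac_gt, frac_lt = gt / s, lt / s
        if max(frac_gt, frac_lt) >= threshold:
            gi, gj = gene_ids[i], gene_ids[j]
            direction = "gt" if frac_gt >= threshold else "lt"
            if gi > gj:
                gi, gj = gj, gi
                direction = "lt" if direction == "gt" else "gt"
            out[(gi, gj)] = (direction, max(frac_gt, frac_lt))
    return out


def naive_reversal_pairs(x0, x1, gene_ids, threshold):
    """{(gene_a, gene_b): (cons0, cons1)} with gene_a class-0-high."""
    x0 = np.asarray(x0, float)
    x1 = np.asarray(x1, float)
    s0, s1 = x0.shape[1], x1.shape[1]
    out = {}
    for i, j in combinations(range(len(gene_ids)), 2):
        f0_gt = (x0[i] > x0[j]).sum() / s0
        f0_lt = (x0[i] < x0[j]).sum() / s0
        f1_gt = (x1[i] > x1[j]).sum() / s1
        f1_lt = (x1[i] < x1[j]).sum() / s1
        if f0_gt > threshold and f1_lt > threshold:
            out[(gene_ids[i], gene_ids[j])] = (f0_gt, f1_lt)
        elif f0_lt > threshold and f1_gt > threshold:
            out[(gene_ids[j], gene_ids[i])] = (f0_lt, f1_gt)
    return out


def naive_avg_rank_diff_score(x0, x1, ia, ib):
    """avgRij by ranking every sample column with naive_ranks."""
    means = []
    for x in (x0, x1):
        diffs = []
        for col in range(x.shape[1]):
            r = naive_ranks(x[:, col])
            diffs.append(abs(r[ia] - r[ib]))
        means.append(sum(diffs) / len(diffs))
    return means[0] * means[1]


def naive_rank_product(fc):
    """(rp_up, rp_down) geometric means of per-pair fold-change ranks."""
    fc = np.asarray(fc, float)
    n_genes, n_pairs = fc.shape
    rp_up = np.ones(n_genes)
    rp_down = np.ones(n_genes)
    for c in range(n_pairs):
        r_down = naive_ranks(fc[:, c])
        r_up = naive_ranks(-fc[:, c])
        rp_up *= r_up
        rp_down *= r_down
    return rp_up ** (1 / n_pairs), rp_down ** (1 / n_pairs)
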