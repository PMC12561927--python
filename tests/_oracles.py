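"""Independent brute-force oracles used by the test suite.

Deliberately naive O(n^2) implementations that never share code with the
package paths they check.
"""

from __future__ import annotations

import math


def brute_merge(intervals, gap=0):
    """Pairwise coalescence to a fixpoint; intervals are (chrom, start, end)."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        used = [False] * len(items)
        for i in range(len(items)):
            if used[i]:
                continue
            c, s, e = items[i]
            for j in range(i + 1, len(items)):
                if used[j]:
                    continue
                c2, s2, e2 = items[j]
                if c == c2 and s2 <= e + gap and s <= e2 + gap:
                    s, e = min(s, s2), max(e, e2)
                    used[j] = True
                    changed = True
            out.append([c, s, e])
        items = out
    return sorted(tuple(x) for x in items)


def overlaps(a, b):
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def brute_overlap_pairs(a_list, b_list, min_frac=0.0):
    pairs = []
    for i, a in enumerate(a_list):
        for j, b in enumerate(b_list):
            if not overlaps(a, b):
                continue
            ov = min(a[2], b[2]) - max(a[1], b[1])
            if ov >= 1 and ov >= min_frac * (b[2] - b[1]):
                pairs.append((i, j, ov))
    return sorted(pairs)


def brute_consensus(master, sample_sets, k):
    kept = []
    for m in master:
        support = sum(
            any(overlaps(m, s) for s in sample)
            for sample in sample_sets
        )
        if support >= k:
            kept.append((m, support))
    return kept


def brute_subtract(query, blacklist):
    return [q for q in query if not any(overlaps(q, b) for b in blacklist)]


def brute_closest(start, tss_list):
    """tss_list: (gene_id, pos). Returns (gene, signed distance) with the
    tie rules: smaller |d|, then smaller position, then smaller gene_id."""
    best = None
    for gene, pos in tss_list:
        d = pos - start
        key = (abs(d), pos, gene)
        if best is None or key < best[0]:
            best = (key, gene, d)
    return best[1], best[2]


def brute_count_overlaps(fragments, regions):
    counts = [0] * len(regions)
    for f in fragments:
        for i, r in enumerate(regions):
            if overlaps(f, r):
                counts[i] += 1
    return counts


def fisher_two_sided(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum of hypergeometric point probabilities
    at most as large as the observed table's (with the standard relative-error
    guard)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_choose(m, k):
        return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

    def log_prob(x):
        return (log_choose(row1, x) + log_choose(row2, col1 - x)
                - log_choose(n, col1))

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)


def wilcoxon_exact_two_sided(x, y):
    """Full enumeration over all rank assignments (no ties)."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n1 = len(x)
    all_ranks = list(range(1, len(pooled) + 1))
    ws = [sum(c) for c in combinations(all_ranks, n1)]
    mean_w = n1 * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(ws)
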