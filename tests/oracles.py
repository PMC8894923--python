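"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: plain
dictionaries, explicit loops, union-find merging, exact combinatorial sums.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np


def site_dict(table, context):
    out = {}
    for r in table.df.itertuples(index=False):
        if r.context == context:
            out[(r.chrom, r.pos, r.strand)] = (r.count_m, r.count_u)
    return out


def brute_bin_levels(table, context, bin_size, min_cov):
    """bin key -> (n_covered, sum_m, sum_t, level or None)."""
    acc = defaultdict(lambda: [0, 0, 0])
    for r in table.df.itertuples(index=False):
        if r.context != context:
            continue
        cov = r.count_m + r.count_u
        key = (r.chrom, (r.pos // bin_size) * bin_size)
        if cov >= min_cov:
            acc[key][0] += 1
            acc[key][1] += r.count_m
            acc[key][2] += cov
        else:
            acc[key]  # bin exists even without covered sites
    out = {}
    for key, (n, sm, st) in acc.items():
        out[key] = (n, sm, st, (sm / st) if st > 0 else None)
    return out


def brute_dmcs(table_a, table_b, context, threshold, min_cov):
    """site key -> signed direction of a DMC (only DMC sites included)."""
    a = site_dict(table_a, context)
    b = site_dict(table_b, context)
    out = {}
    for key in set(a) & set(b):
        ma, ua = a[key]
        mb, ub = b[key]
        if ma + ua < min_cov or mb + ub < min_cov:
            continue
        delta = mb / (mb + ub) - ma / (ma + ua)
        if abs(delta) >= threshold:
            out[key] = 1 if delta > 0 else -1
    return out


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def brute_merge(candidates, merge_gap):
    """candidates: list of (chrom, start, end, delta); all-pairs union-find.

    Returns DMR intervals [(chrom, start, end, member_indices)] for clusters
    of >= 2 bins, sorted.
    """
    uf = UnionFind(len(candidates))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            ci, cj = candidates[i], candidates[j]
            if ci[0] != cj[0]:
                continue
            gap = max(cj[1] - ci[2], ci[1] - cj[2])
            if gap <= merge_gap:
                uf.union(i, j)
    clusters = defaultdict(list)
    for i in range(len(candidates)):
        clusters[uf.find(i)].append(i)
    dmrs = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda i: candidates[i][1])
        chrom = candidates[members[0]][0]
        start = min(candidates[i][1] for i in members)
        end = max(candidates[i][2] for i in members)
        dmrs.append((chrom, start, end, tuple(members)))
    return sorted(dmrs)


def brute_force_call_dmrs(control, treated, *, context, direction, min_dmc, min_diff,
                          merge_gap, bin_size, min_cov):
    """Full reference DMR caller: per-bin check + union-find merge + singleton
    discard.  Returns [(chrom, start, end, member_bin_starts)]."""
    sign = -1 if direction == "hypo" else 1
    bins_a = brute_bin_levels(control, context, bin_size, min_cov)
    bins_b = brute_bin_levels(treated, context, bin_size, min_cov)
    dmcs = brute_dmcs(control, treated, context, min_diff, min_cov)
    dmc_per_bin = defaultdict(int)
    for (chrom, pos, _strand), d in dmcs.items():
        if d == sign:
            dmc_per_bin[(chrom, (pos // bin_size) * bin_size)] += 1
    candidates = []
    for key in sorted(set(bins_a) & set(bins_b)):
        la = bins_a[key][3]
        lb = bins_b[key][3]
        if la is None or lb is None:
            continue
        delta = lb - la
        if sign * delta < min_diff:
            continue
        if dmc_per_bin.get(key, 0) < min_dmc:
            continue
        candidates.append((key[0], key[1], key[1] + bin_size, delta))
    merged = brute_merge(candidates, merge_gap)
    out = []
    for chrom, start, end, members in merged:
        out.append((chrom, start, end, tuple(candidates[i][1] for i in members)))
    return out


def hypergeom_upper_tail(n, size_a, size_b, observed):
    """P(|A ∩ B| >= observed) by direct exact summation (Fractions-free:
    math.comb keeps it exact until the final division)."""
    total = 0
    hi = min(size_a, size_b)
    denom = math.comb(n, size_b)
    for i in range(observed, hi + 1):
        total += math.comb(size_a, i) * math.comb(n - size_a, size_b - i)
    return total / denom


def monte_carlo_multiset_tail(rng, n, sizes, observed, n_draws=100_000):
    """MC estimate (and SE) of P(|∩ S_i| >= observed) for uniform subsets."""
    member = []
    for s in sizes:
        u = rng.random((n_draws, n))
        ranks = np.argpartition(u, s - 1, axis=1)[:, :s]
        m = np.zeros((n_draws, n), dtype=bool)
        np.put_along_axis(m, ranks, True, axis=1)
        member.append(m)
    inter = member[0]
    for m in member[1:]:
        inter = inter & m
    counts = inter.sum(axis=1)
    hits = (counts >= observed).mean()
    se = math.sqrt(max(hits * (1 - hits), 1e-12) / n_draws)
    return hits, se
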