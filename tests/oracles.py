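"""Independent brute-force oracles used to validate the interval algebra and
rank tests.  These deliberately share no code with the implementation:
interval questions are answered by all-pairs arithmetic or per-base coverage
counting, and rank-test p-values by exhaustive enumeration of the null."""

from __future__ import annotations

import itertools
import math

import numpy as np

from g4shift.intervals import GenomicInterval, IntervalSet


def brute_window_overlap(query, features, w):
    """All-pairs check: query iv reported iff [start-w, end+w) hits any feature."""
    feats = list(features)
    out = []
    for q in query:
        qs, qe = q.start - w, q.end + w
        if any(f.chrom == q.chrom and f.start < qe and qs < f.end for f in feats):
            out.append(q)
    return out


def brute_merge(intervals, gap):
    """Union by per-base painting (gap fuses runs separated by <= gap bases)."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        covered = set()
        for s, e in by_chrom[chrom]:
            covered.update(range(s, e))
        if not covered:
            continue
        positions = sorted(covered)
        run_start = positions[0]
        prev = positions[0]
        for p in positions[1:]:
            if p - prev - 1 <= gap:
                prev = p
            else:
                out.append((chrom, run_start, prev + 1))
                run_start = prev = p
        out.append((chrom, run_start, prev + 1))
    return out


def brute_consensus(sets, k):
    """Bases covered by >= k sets, via literal per-base counting."""
    chroms = sorted({iv.chrom for s in sets for iv in s})
    out = []
    for chrom in chroms:
        counts = {}
        for s in sets:
            bases = set()
            for iv in s.by_chrom(chrom):
                bases.update(range(iv.start, iv.end))
            for b in bases:
                counts[b] = counts.get(b, 0) + 1
        good = sorted(b for b, c in counts.items() if c >= k)
        if not good:
            continue
        run_start = prev = good[0]
        for b in good[1:]:
            if b == prev + 1:
                prev = b
            else:
                out.append((chrom, run_start, prev + 1))
                run_start = prev = b
        out.append((chrom, run_start, prev + 1))
    return out


def brute_nearest_distance(q, features):
    """Smallest w such that the w-extension of q touches a feature (0 = overlap)."""
    best = None
    for f in features:
        if f.chrom != q.chrom:
            continue
        if f.start < q.end and q.start < f.end:
            d = 0
        elif f.start >= q.end:
            d = f.start - q.end + 1
        else:
            d = q.start - f.end + 1
        best = d if best is None else min(best, d)
    return best


def random_interval_set(rng, genome, n_max=200, width_max=30, role="events"):
    names = [c for c, _ in genome.chroms]
    lengths = genome.lengths
    n = int(rng.integers(1, n_max + 1))
    out = []
    for _ in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        width = int(rng.integers(1, width_max + 1))
        start = int(rng.integers(0, lengths[chrom] - width))
        out.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(out, genome, role)


# -- rank-test enumeration ---------------------------------------------------


def enum_mannwhitney_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Requires tie-free pooled data.  Two-sided p = 2 * min(P(U <= u), P(U >= u))
    under the exact permutation null, capped at 1.
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n + m, "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + m + 1), n):
        us.append(sum(combo) - n * (n + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def enum_wilcoxon_p(x, mu0=0.0):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.array([v - mu0 for v in x], dtype=float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    assert len(set(absd)) == n, "oracle requires tie-free |deviations|"
    ranks = np.argsort(np.argsort(absd)) + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))
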