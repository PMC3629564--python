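"""Independent brute-force reference implementations used by the tests.

These deliberately use naive loops and textbook formulas so that they are
independent of the vectorized/library code paths they check.  The peak
oracle shares the per-gene randomization stream with the caller (both draw
the placement matrix as one ``integers`` call), as required for an exact
comparison.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

from aluclip.core import CrosslinkTrack, GeneModel
from aluclip.peaks import gene_rng


def naive_heights(events: dict[int, int], gene_start: int, gene_end: int, flank: int) -> dict[int, int]:
    """O(L^2) windowed heights at each crosslinked position."""
    heights = {}
    for p in events:
        total = 0
        for q, n in events.items():
            if abs(q - p) <= flank and gene_start <= q < gene_end:
                total += n
        heights[p] = total
    return heights


def brute_force_sites(
    track: CrosslinkTrack,
    gene: GeneModel,
    gene_index: int,
    flank: int,
    fdr_threshold: float,
    iterations: int,
    seed: int,
):
    """Naive site calls for one gene, sharing the caller's randomization.

    Returns a list of (start, end, summit, event_count, fdr) tuples.
    """
    events = dict(track.positions_in(gene.contig, gene.strand, gene.start, gene.end))
    if not events:
        return []
    L = gene.length
    n = sum(events.values())
    heights = naive_heights(events, gene.start, gene.end, flank)

    rng = gene_rng(seed, gene_index)
    placements = rng.integers(0, L, size=(iterations, n))

    thresholds = sorted(set(heights.values()))
    obs_ge = {h: sum(1 for v in heights.values() if v >= h) for h in thresholds}
    rand_ge = {h: 0 for h in thresholds}
    for it in range(iterations):
        rand_events: dict[int, int] = {}
        for p in placements[it]:
            rand_events[int(p) + gene.start] = rand_events.get(int(p) + gene.start, 0) + 1
        rand_heights = naive_heights(rand_events, gene.start, gene.end, flank)
        for h in thresholds:
            rand_ge[h] += sum(1 for v in rand_heights.values() if v >= h)

    fdr_table = {}
    prev = None
    for h in thresholds:
        f = min(rand_ge[h] / iterations / obs_ge[h], 1.0)
        if prev is not None:
            f = min(f, prev)
        fdr_table[h] = f
        prev = f

    significant = sorted(p for p in events if fdr_table[heights[p]] < fdr_threshold)
    sites = []
    if not significant:
        return sites
    cluster = [significant[0]]
    clusters = []
    for p in significant[1:]:
        if p - cluster[-1] <= flank:
            cluster.append(p)
        else:
            clusters.append(cluster)
            cluster = [p]
    clusters.append(cluster)
    for cl in clusters:
        start, end = cl[0], cl[-1] + 1
        members = [p for p in events if start <= p < end]
        count = sum(events[p] for p in members)
        best = max(events[p] for p in members)
        cands = [p for p in members if events[p] == best]
        summit = min(cands) if gene.strand == "+" else max(cands)
        fdr = min(fdr_table[heights[p]] for p in members)
        sites.append((start, end, summit, count, fdr))
    return sites


def naive_size_factors(matrix) -> list[float]:
    """Median-of-ratios with explicit loops and stdlib statistics."""
    rows = [list(map(float, row)) for row in matrix]
    usable = [row for row in rows if all(v > 0 for v in row)]
    n_samples = len(rows[0])
    factors = []
    for j in range(n_samples):
        ratios = []
        for row in usable:
            geomean = math.prod(row) ** (1.0 / n_samples)
            ratios.append(row[j] / geomean)
        factors.append(statistics.median(ratios))
    return factors


def textbook_chi2_yates(table) -> float:
    """2x2 chi-square p-value with Yates continuity correction, by formula."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row = [a + b, c + d]
    col = [a + c, b + d]
    stat = 0.0
    for i, (x, y) in enumerate(((a, b), (c, d))):
        for j, obs in enumerate((x, y)):
            exp = row[i] * col[j] / n
            stat += (abs(obs - exp) - 0.5) ** 2 / exp
    return float(chi2_dist.sf(stat, df=1))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    K = a + b          # row 1 total
    N1 = a + c         # col 1 total
    rv = hypergeom(n, K, N1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, N1 - (c + d)), min(K, N1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return float(min(total, 1.0))
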