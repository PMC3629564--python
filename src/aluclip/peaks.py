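"""Binding-site calling by gene-wise randomization FDR.

For each crosslinked position the local *height* is the number of events
within a flank window; significance is assessed against randomized tracks
in which the gene's events are re-placed uniformly at random within the
gene.  Significant positions within a flank of each other merge into one
binding site.  The hnRNP C defaults are flank 10 nt with FDR < 5%; the
more focused U2AF65 uses flank 5 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .core import BindingSite, CrosslinkTrack, GeneModel


@dataclass
class PeakParams:
    flank: int = 10
    fdr_threshold: float = 0.05
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    """Deterministic per-gene randomization stream.

    Both the caller and any independent re-implementation sharing the seed
    must draw the randomized placements as a single
    ``rng.integers(0, L, size=(iterations, n))`` call from this stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(gene_index,))
    )


def window_heights(
    positions: np.ndarray, counts: np.ndarray, gene_start: int, gene_end: int, flank: int
) -> np.ndarray:
    """Height per crosslinked position: events within +-flank, clipped to the gene."""
    positions = np.asarray(positions, dtype=int)
    counts = np.asarray(counts, dtype=int)
    if len(positions) == 0:
        return np.zeros(0, dtype=int)
    L = gene_end - gene_start
    arr = np.zeros(L, dtype=np.int64)
    arr[positions - gene_start] = counts
    csum = np.concatenate([[0], np.cumsum(arr)])
    lo = np.clip(positions - gene_start - flank, 0, L)
    hi = np.clip(positions - gene_start + flank + 1, 0, L)
    return csum[hi] - csum[lo]


def _heights_full(arr: np.ndarray, flank: int) -> np.ndarray:
    """Windowed sums at every position of a dense count array."""
    L = len(arr)
    csum = np.concatenate([[0], np.cumsum(arr)])
    idx = np.arange(L)
    lo = np.clip(idx - flank, 0, L)
    hi = np.clip(idx + flank + 1, 0, L)
    return csum[hi] - csum[lo]


def empirical_fdr(
    positions: np.ndarray,
    counts: np.ndarray,
    gene_start: int,
    gene_end: int,
    flank: int,
    iterations: int,
    rng: np.random.Generator,
) -> dict[int, float]:
    """FDR as a function of observed height.

    ``n`` events are placed uniformly at random (with replacement) over the
    gene for each iteration; FDR(h) is the mean randomized count of
    crosslinked positions with height >= h divided by the observed count,
    capped at 1 and made monotone non-increasing in h.
    """
    L = gene_end - gene_start
    if L <= 0:
        raise ValueError("zero-length gene")
    counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    if n == 0:
        return {}
    obs_heights = window_heights(positions, counts, gene_start, gene_end, flank)
    thresholds = np.unique(obs_heights)                       # ascending
    obs_ge = np.array([(obs_heights >= h).sum() for h in thresholds])

    placements = rng.integers(0, L, size=(iterations, n))
    rand_ge = np.zeros(len(thresholds))
    for it in range(iterations):
        arr = np.bincount(placements[it], minlength=L)
        h_full = _heights_full(arr, flank)
        # positions, not events: each crosslinked position counted once
        rand_heights = np.sort(h_full[arr > 0])
        rand_ge += len(rand_heights) - np.searchsorted(rand_heights, thresholds, side="left")
    fdr = np.minimum(rand_ge / iterations / obs_ge, 1.0)
    # cap then enforce monotone non-increasing in h
    fdr = np.minimum.accumulate(fdr)
    return {int(h): float(f) for h, f in zip(thresholds, fdr)}


def assign_events_to_genes(
    track: CrosslinkTrack, genes: list[GeneModel]
) -> tuple[dict[str, list[tuple[int, int]]], int]:
    """Partition track events by gene.

    Events match a gene on the same strand; where same-strand genes overlap
    the longest gene wins.  Events on a strand with no matching gene are
    ignored and tallied.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        trees.setdefault((g.contig, g.strand), IntervalTree()).addi(g.start, g.end, g)
    by_gene: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    n_ignored = 0
    for contig, strand in track.keys():
        tree = trees.get((contig, strand))
        for pos, n in sorted(track.counts(contig, strand).items()):
            hits = [iv.data for iv in tree[pos]] if tree is not None else []
            if not hits:
                n_ignored += n
                continue
            best = max(hits, key=lambda g: (g.length, g.gene_id))
            by_gene[best.gene_id].append((pos, n))
    return by_gene, n_ignored


def _merge_significant(sig_positions: np.ndarray, flank: int) -> list[tuple[int, int]]:
    """Merge sorted significant positions within <= flank nt into intervals."""
    clusters = []
    start = prev = int(sig_positions[0])
    for p in sig_positions[1:]:
        p = int(p)
        if p - prev <= flank:
            prev = p
        else:
            clusters.append((start, prev + 1))
            start = prev = p
    clusters.append((start, prev + 1))
    return clusters


def call_binding_sites(
    track: CrosslinkTrack, genes: list[GeneModel], params: PeakParams
) -> list[BindingSite]:
    """Call significant binding sites gene by gene.

    Positions whose height FDR falls below the threshold are significant;
    significant positions within <= flank nt merge into one site spanning
    their outermost positions.  The summit is the member position with the
    most crosslink events, ties broken toward the 5'-most position in
    transcript orientation.  Deterministic for a fixed seed: each gene uses
    the stream from :func:`gene_rng` keyed by its index in the sorted gene
    list.
    """
    genes_sorted = sorted(genes, key=lambda g: g.gene_id)
    by_gene, _ = assign_events_to_genes(track, genes_sorted)
    sites: list[BindingSite] = []
    for gi, gene in enumerate(genes_sorted):
        events = by_gene[gene.gene_id]
        if not events:
            continue
        positions = np.array([p for p, _ in events])
        counts = np.array([n for _, n in events])
        rng = gene_rng(params.seed, gi)
        fdr_table = empirical_fdr(
            positions, counts, gene.start, gene.end,
            params.flank, params.iterations, rng,
        )
        heights = window_heights(positions, counts, gene.start, gene.end, params.flank)
        fdrs = np.array([fdr_table[int(h)] for h in heights])
        sig = fdrs < params.fdr_threshold
        if not sig.any():
            continue
        sig_pos = positions[sig]
        pos_to_count = dict(zip(positions.tolist(), counts.tolist()))
        pos_to_fdr = dict(zip(positions.tolist(), fdrs.tolist()))
        for start, end in _merge_significant(sig_pos, params.flank):
            members = [p for p in pos_to_count if start <= p < end]
            best = max(pos_to_count[p] for p in members)
            candidates = [p for p in members if pos_to_count[p] == best]
            summit = min(candidates) if gene.strand == "+" else max(candidates)
            # FDR of the site's maximal height = smallest member FDR
            site_fdr = min(pos_to_fdr[p] for p in members)
            sites.append(
                BindingSite(
                    contig=gene.contig, strand=gene.strand, start=start, end=end,
                    summit=summit,
                    event_count=int(sum(pos_to_count[p] for p in members)),
                    fdr=float(site_fdr), gene_id=gene.gene_id,
                )
            )
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites
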