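"""Positional summaries around splice sites and crosslink nucleotides.

RNA maps aggregate crosslink events at offsets relative to a splice-site
anchor in transcript orientation (offset 0 = first/last exonic
nucleotide); heatmap matrices keep per-exon rows.  Pentamer enrichment
contrasts the 5-mer spectrum around crosslink sites with a within-gene
uniform randomization, and co-binding profiles count other-RBP sites
around binding-site summits normalized to distal background windows.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .core import BindingSite, CrosslinkTrack, GeneModel, revcomp

PENTAMERS = ["".join(p) for p in product("ACGT", repeat=5)]


def _anchor_position(exon, anchor: str) -> int:
    """Genomic position of offset 0 for an exon-like record.

    ``3ss``: first exonic nucleotide in transcript orientation;
    ``5ss``: last exonic nucleotide.
    """
    if anchor == "3ss":
        return exon.start if exon.strand == "+" else exon.end - 1
    if anchor == "5ss":
        return exon.end - 1 if exon.strand == "+" else exon.start
    raise ValueError(f"unknown anchor {anchor!r}")


def _offsets_to_genomic(anchor_pos: int, strand: str, offsets: np.ndarray) -> np.ndarray:
    return anchor_pos + offsets if strand == "+" else anchor_pos - offsets


def exon_offset_matrix(
    exons: list, track: CrosslinkTrack, window: tuple[int, int], anchor: str = "3ss"
) -> pd.DataFrame:
    """Per-exon crosslink events at each offset of the window.

    ``window`` is (lo, hi) inclusive in transcript orientation; rows are
    exons in input order, columns the offsets lo..hi.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    rows = []
    for exon in exons:
        anchor_pos = _anchor_position(exon, anchor)
        gpos = _offsets_to_genomic(anchor_pos, exon.strand, offsets)
        counts = [track.count_at(exon.contig, exon.strand, int(p)) for p in gpos]
        rows.append(counts)
    ids = [getattr(e, "exon_id", f"exon{i}") for i, e in enumerate(exons)]
    return pd.DataFrame(rows, index=ids, columns=offsets)


def rna_map(
    exons: list,
    track: CrosslinkTrack,
    window: tuple[int, int],
    anchor: str = "3ss",
    mode: str = "percentage",
    size_factor: float = 1.0,
) -> pd.Series:
    """Per-offset summary across exons.

    ``percentage``: percent of exons with at least one crosslink event at
    the offset; ``total``: summed events, divided by the track's size
    factor to correct for library size.
    """
    if not exons:
        raise ValueError("empty exon set")
    mat = exon_offset_matrix(exons, track, window, anchor)
    if mode == "percentage":
        return (mat > 0).mean(axis=0) * 100.0
    if mode == "total":
        return mat.sum(axis=0) / size_factor
    raise ValueError(f"unknown mode {mode!r}")


def splice_site_heatmap(
    exons: list,
    tracks: dict[str, CrosslinkTrack],
    filter_track: str,
    window: tuple[int, int] = (-50, 10),
    min_events: int = 5,
    anchor: str = "3ss",
    sort_key: list[float] | None = None,
    sort_descending: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-track exon-by-offset matrices with a shared, filtered row order.

    Rows are exons with at least ``min_events`` crosslink events of the
    designated filter track within the window; the same rows, in the same
    order, appear in every returned matrix.  ``sort_key`` (one value per
    input exon, e.g. the inclusion fold change) orders the rows.
    """
    mats = {name: exon_offset_matrix(exons, trk, window, anchor) for name, trk in tracks.items()}
    keep = mats[filter_track].sum(axis=1) >= min_events
    order = np.arange(len(exons))[keep.to_numpy()]
    if sort_key is not None:
        key = np.asarray(sort_key, dtype=float)[order]
        sub = np.argsort(key, kind="stable")
        order = order[sub[::-1] if sort_descending else sub]
    return {name: mat.iloc[order] for name, mat in mats.items()}


def _pentamer_counts(
    events_by_gene: dict[str, list[tuple[int, int]]],
    genes_by_id: dict[str, GeneModel],
    genome: dict[str, str],
    flank: int,
) -> np.ndarray:
    """Event-weighted counts of 5-mers covering any position within
    +-flank of a crosslink nucleotide, on the transcript strand."""
    index = {p: i for i, p in enumerate(PENTAMERS)}
    counts = np.zeros(len(PENTAMERS))
    for gene_id, events in events_by_gene.items():
        gene = genes_by_id[gene_id]
        plus = genome[gene.contig][gene.start : gene.end]
        tx_seq = plus if gene.strand == "+" else revcomp(plus)
        L = len(tx_seq)
        for pos, weight in events:
            t = pos - gene.start if gene.strand == "+" else gene.end - 1 - pos
            # pentamer start offsets covering [t-flank, t+flank]
            for s in range(max(0, t - flank - 4), min(L - 4, t + flank + 1)):
                kmer = tx_seq[s : s + 5]
                idx = index.get(kmer)
                if idx is not None:
                    counts[idx] += weight
    return counts


def pentamer_enrichment(
    track: CrosslinkTrack,
    genome: dict[str, str],
    genes: list[GeneModel],
    flank: int = 10,
    iterations: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Fold enrichment of each pentamer around crosslink sites.

    Observed counts use all 5-mers (transcript strand) covering any
    position within +-flank of a crosslink nucleotide, weighted by event
    count; expected counts repeat the computation with the same number of
    events per gene placed uniformly at random, averaged over iterations
    and floored at one occurrence.
    """
    from .peaks import assign_events_to_genes

    by_gene, _ = assign_events_to_genes(track, genes)
    by_gene = {g: ev for g, ev in by_gene.items() if ev}
    if not by_gene:
        raise ValueError("track has no events within the given genes")
    genes_by_id = {g.gene_id: g for g in genes}
    observed = _pentamer_counts(by_gene, genes_by_id, genome, flank)

    rng = np.random.default_rng(seed)
    expected = np.zeros(len(PENTAMERS))
    for _ in range(iterations):
        rand_by_gene = {}
        for gene_id, events in sorted(by_gene.items()):
            gene = genes_by_id[gene_id]
            n = sum(w for _, w in events)
            pos = rng.integers(gene.start, gene.end, size=n)
            rand_by_gene[gene_id] = [(int(p), 1) for p in pos]
        expected += _pentamer_counts(rand_by_gene, genes_by_id, genome, flank)
    expected /= iterations
    enrichment = observed / np.maximum(expected, 1.0)
    return pd.Series(enrichment, index=PENTAMERS)


def rbp_overlap_profile(
    sites: list[BindingSite],
    other_sites: list[BindingSite],
    half_window: int = 100,
    background_offsets: tuple[tuple[int, int], tuple[int, int]] = ((-99, -90), (90, 99)),
) -> tuple[pd.Series, pd.Series, bool]:
    """Frequency of other-RBP sites at offsets around binding-site summits.

    Per offset o in [-half_window, half_window] (transcript orientation),
    the raw frequency is the fraction of summits with an other-RBP site
    covering summit + o on the same strand.  The profile is normalized to
    the mean frequency over two distal 10-nt background windows; a zero
    background flags the normalized profile undefined.

    Returns (normalized profile, raw frequency, background_defined).
    """
    if not sites:
        raise ValueError("empty summit set")
    offsets = np.arange(-half_window, half_window + 1)
    cover: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in other_sites:
        cover.setdefault((s.contig, s.strand), []).append((s.start, s.end))
    freq = np.zeros(len(offsets))
    for site in sites:
        gpos = _offsets_to_genomic(site.summit, site.strand, offsets)
        ivs = cover.get((site.contig, site.strand), [])
        for k, p in enumerate(gpos):
            if any(bs <= p < be for bs, be in ivs):
                freq[k] += 1
    freq /= len(sites)
    raw = pd.Series(freq, index=offsets)
    bg_mask = np.zeros(len(offsets), dtype=bool)
    for lo, hi in background_offsets:
        bg_mask |= (offsets >= lo) & (offsets <= hi)
    background = raw[bg_mask].mean()
    if background == 0:
        return raw * np.nan, raw, False
    return raw / background, raw, True
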