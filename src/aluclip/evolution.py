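"""Consensus mapping of Alu elements and the U-tract selection statistic.

Each repeat element is aligned pairwise to the family consensus to map
its positions onto consensus coordinates; splice sites of exonized
elements and the upstream/linker U-tract regions are then localized on
the consensus.  The selection statistic compares the cumulative U-tract
length distribution of exonized elements against nonexonized antisense
elements from the same genes: the ratio of the fractions with tracts of
at least L uridines, with a chi-square (or Fisher) p-value per L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .core import AluRecord, GeneModel, revcomp


@dataclass
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class AluElement:
    """A repeat element with its consensus mapping and U-tract lengths."""

    record: AluRecord
    orientation: str = "unclassified"
    mapping: np.ndarray | None = None   # element position -> consensus coord or -1
    upstream_utract: int | None = None
    linker_utract: int | None = None
    exonized: bool = False
    set_label: str | None = None
    gene_ids: list[str] = field(default_factory=list)


def classify_orientation(alu: AluRecord, genes: list[GeneModel]) -> str:
    """sense / antisense / ambiguous / intergenic relative to overlapping genes."""
    strands = {
        g.strand
        for g in genes
        if g.contig == alu.contig and alu.start < g.end and g.start < alu.end
    }
    if not strands:
        return "intergenic"
    if strands == {alu.strand}:
        return "sense"
    if alu.strand not in strands:
        return "antisense"
    return "ambiguous"


def align_to_consensus(
    element_seq: str,
    consensus: str,
    scoring: AlignScoring | None = None,
    length_tolerance: float = 0.15,
) -> np.ndarray:
    """Map each element position to its consensus coordinate (or -1 for gaps).

    Global pairwise alignment with affine gap costs; elements whose length
    deviates from the consensus by more than the tolerance are rejected.
    Biopython's first-reported optimal alignment is used, which breaks
    score ties deterministically.
    """
    if not element_seq:
        raise ValueError("empty element sequence")
    n, m = len(element_seq), len(consensus)
    if abs(n - m) > length_tolerance * m:
        raise ValueError(
            f"element length {n} outside +-{length_tolerance:.0%} of consensus length {m}"
        )
    scoring = scoring or AlignScoring()
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )
    aln = aligner.align(consensus, element_seq)[0]
    mapping = np.full(n, -1, dtype=int)
    cons_blocks, elem_blocks = aln.aligned
    for (c0, c1), (e0, e1) in zip(cons_blocks, elem_blocks):
        mapping[e0:e1] = np.arange(c0, c1)
    return mapping


def element_sequence(alu: AluRecord, genome: dict[str, str]) -> str:
    """Element sequence in consensus orientation (the Alu's own strand)."""
    plus = genome[alu.contig][alu.start : alu.end]
    return plus if alu.strand == "+" else revcomp(plus)


def genomic_to_element(alu: AluRecord, gpos: int) -> int:
    """Genomic position -> element-local index in consensus orientation."""
    if not alu.start <= gpos < alu.end:
        raise ValueError("position outside element")
    return gpos - alu.start if alu.strand == "+" else alu.end - 1 - gpos


def map_splice_sites(
    alu_exons: list[dict],
    elements: dict[str, AluElement],
    linker_boundary: int,
) -> pd.DataFrame:
    """Consensus-coordinate histogram of exon splice sites.

    ``alu_exons``: records with ``alu_name``, ``acceptor``, ``donor``
    (genomic positions) and junction support counts for both sites; exons
    lacking support on either site are excluded.  Sites mapping to an
    alignment gap land in the ``unmapped`` bin (coordinate -1).  Arm
    assignment splits consensus coordinates at ``linker_boundary``.
    """
    rows = []
    for exon in alu_exons:
        if exon.get("acceptor_support", 1) < 1 or exon.get("donor_support", 1) < 1:
            continue
        elem = elements[exon["alu_name"]]
        for side in ("acceptor", "donor"):
            epos = genomic_to_element(elem.record, exon[side])
            cpos = int(elem.mapping[epos]) if elem.mapping is not None else -1
            arm = "unmapped" if cpos < 0 else ("arm1" if cpos < linker_boundary else "arm2")
            rows.append(dict(side=side, consensus_coord=cpos, arm=arm))
    df = pd.DataFrame(rows, columns=["side", "consensus_coord", "arm"])
    return (
        df.groupby(["side", "consensus_coord", "arm"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )


def _longest_a_run_overlapping(seq: str, start: int, end: int) -> int:
    """Longest maximal A-run in ``seq`` overlapping [start, end)."""
    best = 0
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in "Aa":
            j = i
            while j < n and seq[j] in "Aa":
                j += 1
            if i < end and j > start:
                best = max(best, j - i)
            i = j
        else:
            i += 1
    return best


def extract_alu_utracts(
    element_seq: str,
    mapping: np.ndarray,
    regions: dict[str, tuple[int, int]],
) -> tuple[int, int]:
    """Upstream and linker U-tract lengths of one element.

    ``element_seq`` is in consensus orientation, in which the transcribed-
    strand U-tracts read as poly(A) blocks; the returned lengths equal the
    transcript-strand U-run lengths.  For each configured consensus-
    coordinate region the longest A-run overlapping the element span that
    aligns into the region is reported; where the whole region aligns to a
    gap, the span between the flanking mapped coordinates is used.
    """
    out = []
    for key in ("upstream_tract", "linker_tract"):
        c0, c1 = regions[key]
        inside = np.nonzero((mapping >= c0) & (mapping < c1))[0]
        if len(inside):
            e0, e1 = int(inside.min()), int(inside.max()) + 1
        else:
            before = np.nonzero((mapping >= 0) & (mapping < c0))[0]
            after = np.nonzero(mapping >= c1)[0]
            e0 = int(before.max()) + 1 if len(before) else 0
            e1 = int(after.min()) if len(after) else len(element_seq)
        out.append(_longest_a_run_overlapping(element_seq, e0, e1))
    return out[0], out[1]


def utract_ratio(
    exonized_lengths: np.ndarray,
    control_lengths: np.ndarray,
    lengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative-frequency ratio of U-tract lengths, exonized vs. control.

    For each L the ratio is the fraction of exonized elements with a tract
    of at least L uridines over the same fraction in the control set;
    significance comes from Pearson's chi-square on the 2x2 table
    (exonized/control x >=L / <L), or Fisher's exact test when any cell is
    below five.  An empty control fraction leaves the ratio undefined
    (NaN) and flagged.
    """
    exonized = np.asarray(exonized_lengths)
    control = np.asarray(control_lengths)
    if lengths is None:
        lengths = np.arange(3, 13)
    rows = []
    for L in lengths:
        a = int((exonized >= L).sum())
        b = len(exonized) - a
        c = int((control >= L).sum())
        d = len(control) - c
        if c == 0 or len(control) == 0 or len(exonized) == 0:
            rows.append(dict(L=int(L), ratio=np.nan, p=np.nan, defined=False,
                             n_exonized=a, n_control=c))
            continue
        ratio = (a / len(exonized)) / (c / len(control))
        table = np.array([[a, b], [c, d]])
        if (table < 5).any():
            p = stats.fisher_exact(table).pvalue
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
        rows.append(dict(L=int(L), ratio=float(ratio), p=float(p), defined=True,
                         n_exonized=a, n_control=c))
    return pd.DataFrame(rows)


def permutation_type1_rate(
    lengths_by_gene: list[tuple[np.ndarray, np.ndarray]],
    L: int | list[int],
    iterations: int = 500,
    seed: int = 0,
) -> float:
    """Type-I rate of the selection statistic under within-gene label shuffles.

    ``lengths_by_gene``: per gene, (exonized tract lengths, control tract
    lengths).  Each permutation swaps the two labels within each gene at
    random and recomputes the 2x2 test; the returned rate is the fraction
    of (permutation, L) tests with p < 0.05.  Passing several L values
    averages over the grid, which smooths the discrete lattice of the
    conditional permutation distribution at any single cutoff.
    """
    Ls = [L] if np.isscalar(L) else list(L)
    rng = np.random.default_rng(seed)
    hits = tested = 0
    for _ in range(iterations):
        ex_parts, ct_parts = [], []
        for ex, ct in lengths_by_gene:
            if rng.random() < 0.5:
                ex, ct = ct, ex
            ex_parts.append(np.asarray(ex))
            ct_parts.append(np.asarray(ct))
        res = utract_ratio(np.concatenate(ex_parts), np.concatenate(ct_parts), Ls)
        for row in res.itertuples(index=False):
            if row.defined:
                tested += 1
                if row.p < 0.05:
                    hits += 1
    return hits / tested if tested else float("nan")
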