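"""Raw-read and alignment preprocessing for iCLIP.

Reads carry a composite barcode: a random barcode used to remove PCR
duplicates and an experimental barcode used for multiplexing.  After
demultiplexing, alignments collapse to unique crosslink events and each
event is assigned the nucleotide immediately 5' of the read start — the
cDNA-truncation convention of iCLIP.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from intervaltree import IntervalTree

from Bio import SeqIO

from .core import CrosslinkTrack, GeneModel

DEFAULT_LAYOUT = "NNNXXXXNN"  # 3 random + 4 experimental + 2 random nt


@dataclass
class BarcodeScheme:
    """Barcode layout read 5'->3': N = random position, X = experimental.

    The default layout places a 4-nt experimental barcode inside a 5-nt
    random barcode; the exact order within the read is configurable.
    """

    layout: str = DEFAULT_LAYOUT
    sample_table: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layout or set(self.layout) - {"N", "X"}:
            raise ValueError("layout must be a non-empty string over {N, X}")
        xpos = self.x_positions
        if xpos and xpos != list(range(xpos[0], xpos[0] + len(xpos))):
            raise ValueError("experimental-barcode positions must be contiguous")
        for bc in self.sample_table:
            if len(bc) != len(xpos):
                raise ValueError(
                    f"barcode {bc!r} length does not match layout ({len(xpos)} X positions)"
                )

    @property
    def x_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.layout) if c == "X"]

    @property
    def n_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.layout) if c == "N"]


class DemuxResult(NamedTuple):
    assigned: dict[str, list]     # sample -> list of SeqRecord
    unassigned: list
    n_too_short: int


def demultiplex(reads: Iterable, scheme: BarcodeScheme) -> DemuxResult:
    """Split reads by experimental barcode; keep the random barcode in the name.

    The whole barcode region is stripped from sequence and qualities; the
    random barcode is appended to the read identifier (``name:rbc:TTTAC``).
    Reads shorter than the layout are counted and skipped; reads whose
    experimental barcode is absent from the sample table go to the
    unassigned sink.  Matching is exact.
    """
    assigned: dict[str, list] = {name: [] for name in scheme.sample_table.values()}
    unassigned: list = []
    too_short = 0
    ln = len(scheme.layout)
    for rec in reads:
        seq = str(rec.seq)
        if len(seq) < ln:
            too_short += 1
            continue
        exp_bc = "".join(seq[i] for i in scheme.x_positions)
        rand_bc = "".join(seq[i] for i in scheme.n_positions)
        insert = rec[ln:]
        insert.id = f"{rec.id}:rbc:{rand_bc}"
        insert.name = insert.id
        insert.description = ""
        sample = scheme.sample_table.get(exp_bc)
        if sample is None:
            unassigned.append(insert)
        else:
            assigned[sample].append(insert)
    return DemuxResult(assigned, unassigned, too_short)


def demultiplex_fastq(path: str | Path, scheme: BarcodeScheme) -> DemuxResult:
    """Demultiplex a FASTQ file (gzip allowed by ``.gz`` suffix)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return demultiplex(SeqIO.parse(fh, "fastq"), scheme)


class Alignment(NamedTuple):
    """A genomic alignment span (0-based half-open) with its random barcode."""

    contig: str
    start: int
    end: int
    strand: str
    barcode: str


def read_alignment_tsv(path: str | Path) -> list[Alignment]:
    """Simplified alignment table: contig, start, end, strand, name.

    The random barcode is recovered from the ``:rbc:`` suffix of the name.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, start, end, strand, name = line.rstrip("\n").split("\t")[:5]
            barcode = name.rsplit(":rbc:", 1)[1] if ":rbc:" in name else ""
            out.append(Alignment(contig, int(start), int(end), strand, barcode))
    return out


def read_alignment_sam(path: str | Path) -> list[Alignment]:
    """Read alignments from SAM/BAM via pysam (barcode from the read name)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            name = aln.query_name or ""
            barcode = name.rsplit(":rbc:", 1)[1] if ":rbc:" in name else ""
            out.append(
                Alignment(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    barcode,
                )
            )
    return out


def assign_crosslink(aln: Alignment, contig_length: int | None = None) -> int | None:
    """Crosslink nucleotide: the position immediately 5' of the read start.

    Plus strand -> ``start - 1``; minus strand -> ``end``.  Returns ``None``
    when the position would fall outside the contig.
    """
    if aln.strand == "+":
        pos = aln.start - 1
        return pos if pos >= 0 else None
    pos = aln.end
    if contig_length is not None and pos >= contig_length:
        return None
    return pos


class CollapseResult(NamedTuple):
    track: CrosslinkTrack
    n_events: int
    n_duplicates: int
    n_dropped: int       # crosslink position off-contig
    n_rejected: int      # missing barcode


def collapse_duplicates(
    alignments: Iterable[Alignment],
    contig_lengths: dict[str, int] | None = None,
) -> CollapseResult:
    """Collapse alignments identical in (contig, strand, crosslink, barcode).

    The duplicate key uses the crosslink position rather than the raw span,
    so trimming-length differences do not split duplicates.  Alignments
    without a random barcode are rejected and tallied.
    """
    seen: set[tuple[str, str, int, str]] = set()
    track = CrosslinkTrack()
    n_dup = n_drop = n_rej = n_events = 0
    for aln in alignments:
        if not aln.barcode:
            n_rej += 1
            continue
        clen = contig_lengths.get(aln.contig) if contig_lengths else None
        pos = assign_crosslink(aln, clen)
        if pos is None:
            n_drop += 1
            continue
        key = (aln.contig, aln.strand, pos, aln.barcode)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        track.add(aln.contig, aln.strand, pos)
        n_events += 1
    return CollapseResult(track, n_events, n_dup, n_drop, n_rej)


# -- genomic-region annotation ---------------------------------------------

#: category priority, highest first
REGION_HIERARCHY = [
    "ncRNA", "3utr", "5utr", "exon", "intron", "antisense", "intergenic",
]

#: distance from an exon boundary within which intronic positions are
#: splice-site proximal
NEAR_SS_DISTANCE = 200


class RegionAnnotator:
    """Assigns a genomic position its highest-priority region category.

    The hierarchy is ncRNA > 3'UTR > 5'UTR > exon > intron > antisense >
    intergenic; intronic positions are additionally flagged near-3'ss
    (within 200 nt upstream of an exon start in transcript orientation),
    near-5'ss (within 200 nt downstream of an exon end) or deep-intronic.
    """

    def __init__(self, genes: list[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self._contigs: set[str] = set()
        for g in genes:
            self._contigs.add(g.contig)
            self._trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)

    def annotate(self, contig: str, pos: int, strand: str) -> str:
        if contig not in self._contigs:
            raise KeyError(f"unknown contig {contig!r}")
        hits = [iv.data for iv in self._trees[contig][pos]]
        same = [g for g in hits if g.strand == strand]
        anti = [g for g in hits if g.strand != strand]
        categories = set()
        for g in same:
            categories.add(self._within_gene(g, pos))
        if not same and anti:
            categories.add("antisense")
        if not categories:
            return "intergenic"
        for cat in REGION_HIERARCHY:
            if cat in categories:
                return cat
            if cat == "intron":
                # intron subcategories share the intron priority slot;
                # splice-site proximity wins over deep-intronic
                for sub in ("intron,near-3ss", "intron,near-5ss", "intron,deep"):
                    if sub in categories:
                        return sub
        return "intergenic"

    def _within_gene(self, g: GeneModel, pos: int) -> str:
        if g.biotype in ("ncRNA", "lincRNA", "snoRNA", "miRNA"):
            return "ncRNA"
        if any(s <= pos < e for s, e in g.utr3):
            return "3utr"
        if any(s <= pos < e for s, e in g.utr5):
            return "5utr"
        if any(s <= pos < e for s, e in g.exons):
            return "exon"
        # intronic: classify by distance to the nearest exon boundary
        near3 = near5 = False
        for s, e in g.exons:
            if g.strand == "+":
                if 0 < s - pos <= NEAR_SS_DISTANCE:
                    near3 = True     # upstream of an exon start (acceptor side)
                if 0 < pos - (e - 1) <= NEAR_SS_DISTANCE:
                    near5 = True     # downstream of an exon end (donor side)
            else:
                if 0 < pos - (e - 1) <= NEAR_SS_DISTANCE:
                    near3 = True
                if 0 < s - pos <= NEAR_SS_DISTANCE:
                    near5 = True
        if near3:
            return "intron,near-3ss"
        if near5:
            return "intron,near-5ss"
        return "intron,deep"

    def annotate_track(self, track: CrosslinkTrack) -> dict[str, int]:
        """Event-weighted tally of region categories over a track."""
        tally: dict[str, int] = {}
        for contig, strand in track.keys():
            for pos, n in track.counts(contig, strand).items():
                cat = self.annotate(contig, pos, strand)
                tally[cat] = tally.get(cat, 0) + n
        return tally
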