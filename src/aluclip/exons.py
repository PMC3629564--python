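"""De novo exon filtering, Alu-exon classification and usage testing.

Assembled exon predictions pass three filters — multi-exon transcript,
junction-read support, 25 bp to 10 kb size — and near-identical exons merge
to their outer boundaries.  Exons are assigned to genes, classified as Alu
exons when a supported splice site falls inside an antisense Alu element,
screened for reading-frame disruption, and tested for differential usage
with a contingency-table stand-in whose p-values feed the two-knockdown
conditional-thresholding combiner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AluRecord, GeneModel

logger = logging.getLogger(__name__)

MIN_EXON_LEN = 25
MAX_EXON_LEN = 10_000
MERGE_DISTANCE = 25
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ExonRecord:
    """A candidate exon surviving the prediction filters."""

    contig: str
    start: int
    end: int
    strand: str
    transcript_ids: set[str] = field(default_factory=set)
    acceptor_support: int = 0
    donor_support: int = 0
    gene_id: str | None = None
    discard_reason: str | None = None
    alu_exon: bool = False
    alu_splice_sites: tuple[str, ...] = ()
    frameshift: bool | None = None
    stop_frames: int | None = None
    disrupted: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def splice_site(self, side: str) -> int:
        """Genomic position of the intronic boundary nucleotide.

        ``acceptor`` is the exon-start side in transcript orientation,
        ``donor`` the exon-end side.
        """
        if side == "acceptor":
            return self.start - 1 if self.strand == "+" else self.end
        if side == "donor":
            return self.end if self.strand == "+" else self.start - 1
        raise ValueError(side)


# -- junction support -------------------------------------------------------

class JunctionTable:
    """Junction-spanning read counts keyed by intron interval.

    A junction is the intron it spans: (contig, strand, intron_start,
    intron_end) half-open.  An exon's acceptor is supported by junctions
    ending at its start; its donor by junctions starting at its end.
    """

    def __init__(self, junctions: dict[tuple[str, str, int, int], int]):
        self._by_acceptor: dict[tuple[str, str, int], int] = {}
        self._by_donor: dict[tuple[str, str, int], int] = {}
        for (contig, strand, i0, i1), n in junctions.items():
            if strand == "+":
                donor_key, acceptor_key = (contig, strand, i0), (contig, strand, i1)
            else:
                donor_key, acceptor_key = (contig, strand, i1), (contig, strand, i0)
            self._by_donor[donor_key] = self._by_donor.get(donor_key, 0) + n
            self._by_acceptor[acceptor_key] = self._by_acceptor.get(acceptor_key, 0) + n

    def acceptor_reads(self, contig: str, strand: str, exon_start: int, exon_end: int) -> int:
        pos = exon_start if strand == "+" else exon_end
        return self._by_acceptor.get((contig, strand, pos), 0)

    def donor_reads(self, contig: str, strand: str, exon_start: int, exon_end: int) -> int:
        pos = exon_end if strand == "+" else exon_start
        return self._by_donor.get((contig, strand, pos), 0)


# -- filtering and merging --------------------------------------------------

def filter_exons(transcripts: list[dict], junctions: JunctionTable) -> list[ExonRecord]:
    """Apply the prediction filters then merge near-identical exons.

    Filters, in order: (a) exon belongs to a multi-exon transcript,
    (b) at least one junction-spanning read supports a splice site,
    (c) length within [25 bp, 10 kb].  Overlapping exons whose starts and
    ends are each less than 25 bp apart merge (single linkage) to their
    outermost boundaries, pooling transcript ids and junction support.
    """
    records: list[ExonRecord] = []
    for tx in transcripts:
        exons = tx["exons"]
        if any(exons[i][0] > exons[i + 1][0] for i in range(len(exons) - 1)):
            raise ValueError(f"transcript {tx['transcript_id']} has unsorted exons")
        if len(exons) < 2:
            continue                                   # (a)
        for s, e in exons:
            acc = junctions.acceptor_reads(tx["contig"], tx["strand"], s, e)
            don = junctions.donor_reads(tx["contig"], tx["strand"], s, e)
            if acc + don < 1:
                continue                               # (b)
            if not MIN_EXON_LEN <= e - s <= MAX_EXON_LEN:
                continue                               # (c)
            records.append(
                ExonRecord(
                    contig=tx["contig"], start=s, end=e, strand=tx["strand"],
                    transcript_ids={tx["transcript_id"]},
                    acceptor_support=acc, donor_support=don,
                )
            )
    return merge_exons(records)


def _mergeable(a: ExonRecord, b: ExonRecord) -> bool:
    overlap = a.start < b.end and b.start < a.end
    return (
        overlap
        and a.contig == b.contig
        and a.strand == b.strand
        and abs(a.start - b.start) < MERGE_DISTANCE
        and abs(a.end - b.end) < MERGE_DISTANCE
    )


def merge_exons(records: list[ExonRecord]) -> list[ExonRecord]:
    """Single-linkage merge of near-identical exons to outer boundaries.

    Iterates to a fixpoint so the result is stable under re-merging.
    """
    while True:
        merged = _merge_pass(records)
        if len(merged) == len(records):
            return merged
        records = merged


def _merge_pass(records: list[ExonRecord]) -> list[ExonRecord]:
    records = sorted(records, key=lambda r: (r.contig, r.strand, r.start, r.end))
    merged: list[ExonRecord] = []
    for rec in records:
        target = None
        for prev in reversed(merged):
            if prev.contig != rec.contig or prev.strand != rec.strand:
                break
            if rec.start - prev.start >= MERGE_DISTANCE:
                break      # earlier clusters start even further left

            if _mergeable(prev, rec):
                target = prev
                break
        if target is None:
            merged.append(rec)
        else:
            target.start = min(target.start, rec.start)
            target.end = max(target.end, rec.end)
            target.transcript_ids |= rec.transcript_ids
            target.acceptor_support = max(target.acceptor_support, rec.acceptor_support)
            target.donor_support = max(target.donor_support, rec.donor_support)
    # deduplicate identical intervals produced by distinct transcripts
    out: dict[tuple, ExonRecord] = {}
    for rec in merged:
        key = (rec.contig, rec.strand, rec.start, rec.end)
        if key in out:
            out[key].transcript_ids |= rec.transcript_ids
            out[key].acceptor_support = max(out[key].acceptor_support, rec.acceptor_support)
            out[key].donor_support = max(out[key].donor_support, rec.donor_support)
        else:
            out[key] = rec
    return list(out.values())


# -- gene assignment --------------------------------------------------------

def assign_gene(
    exon: ExonRecord,
    genes: list[GeneModel],
    predicted_models: dict[str, list[tuple[int, int, str, str]]] | None = None,
    transcript_model: dict[str, str] | None = None,
) -> str | None:
    """Assign the exon to a reference gene, or discard it.

    A direct single-gene overlap (same strand) wins; exons overlapping more
    than one gene are discarded.  Intergenic exons inherit a gene through
    their predicted model when that model overlaps exactly one gene.
    ``predicted_models`` maps model id -> list of (start, end, contig,
    strand) spans; ``transcript_model`` maps transcript id -> model id.
    """
    direct = [
        g for g in genes
        if g.contig == exon.contig and g.strand == exon.strand
        and exon.start < g.end and g.start < exon.end
    ]
    if len(direct) == 1:
        exon.gene_id = direct[0].gene_id
        return exon.gene_id
    if len(direct) > 1:
        exon.discard_reason = "overlaps multiple genes"
        return None
    if predicted_models and transcript_model:
        model_ids = {
            transcript_model[t] for t in exon.transcript_ids if t in transcript_model
        }
        hit_genes: set[str] = set()
        for mid in model_ids:
            for s, e, contig, strand in predicted_models.get(mid, []):
                for g in genes:
                    if g.contig == contig and g.strand == strand and s < g.end and g.start < e:
                        hit_genes.add(g.gene_id)
        if len(hit_genes) == 1:
            exon.gene_id = next(iter(hit_genes))
            return exon.gene_id
    exon.discard_reason = exon.discard_reason or "no gene assignment"
    return None


# -- Alu-exon classification ------------------------------------------------

def classify_alu_exon(
    exon: ExonRecord, alus: list[AluRecord], gene_strand: str
) -> bool:
    """Alu exon: a supported splice site inside an antisense Alu element.

    The splice-site position is the intronic boundary nucleotide adjacent
    to the exon; the hosting Alu must lie on the strand opposite the gene,
    and the site needs >= 1 junction-spanning read.
    """
    anti = "-" if gene_strand == "+" else "+"
    hits = []
    for side, support in (
        ("acceptor", exon.acceptor_support),
        ("donor", exon.donor_support),
    ):
        if support < 1:
            continue
        pos = exon.splice_site(side)
        for alu in alus:
            if alu.contig == exon.contig and alu.strand == anti and alu.start <= pos < alu.end:
                hits.append(side)
                break
    exon.alu_exon = bool(hits)
    exon.alu_splice_sites = tuple(hits)
    return exon.alu_exon


# -- disruption prediction --------------------------------------------------

def predict_disruption(
    length: int, tx_seq: str, rule: str | None = None
) -> tuple[bool, int, bool]:
    """Frameshift flag, stop-frame count and combined disruption call.

    A frameshift arises when the exon length is not a multiple of 3; the
    stop-frame count is the number of the three exon-internal reading
    frames containing a stop codon on the transcript strand.  The default
    combination rule flags disruption on frameshift OR stops in all three
    frames.
    """
    if rule is None:
        rule = "frameshift_or_all_frames"
        logger.info(
            "predict_disruption: using default combination rule "
            "'frameshift_or_all_frames' (frameshift OR stop codon in all three frames)"
        )
    frameshift = length % 3 != 0
    seq = tx_seq.upper().replace("U", "T")
    stop_frames = 0
    for frame in range(3):
        codons = (seq[i : i + 3] for i in range(frame, len(seq) - 2, 3))
        if any(c in STOP_CODONS for c in codons):
            stop_frames += 1
    if rule == "frameshift_or_all_frames":
        disrupted = frameshift or stop_frames == 3
    elif rule == "frameshift_or_any_frame":
        disrupted = frameshift or stop_frames >= 1
    else:
        raise ValueError(f"unknown disruption rule {rule!r}")
    return frameshift, stop_frames, disrupted


# -- exon usage test and combiner -------------------------------------------

def exon_usage_test(
    incl_kd: int, gene_kd: int, incl_ctrl: int, gene_ctrl: int
) -> tuple[float, float, bool]:
    """Contingency stand-in test of differential exon usage.

    Tests exon counts against remaining gene counts between one knockdown
    and control: chi-square with continuity correction, or Fisher's exact
    test when any expected cell is below five.  Returns (p-value, fold
    change of normalized exon expression, testable flag).
    """
    if gene_kd <= 0 or gene_ctrl <= 0:
        return 1.0, np.nan, False
    rest_kd = gene_kd - incl_kd
    rest_ctrl = gene_ctrl - incl_ctrl
    if rest_kd < 0 or rest_ctrl < 0:
        raise ValueError("exon counts exceed gene totals")
    table = np.array([[incl_kd, rest_kd], [incl_ctrl, rest_ctrl]])
    if incl_kd + incl_ctrl == 0:
        return 1.0, np.nan, False
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        p = stats.fisher_exact(table).pvalue
    else:
        p = stats.chi2_contingency(table, correction=True).pvalue
    prop_kd = incl_kd / gene_kd
    prop_ctrl = incl_ctrl / gene_ctrl
    fold = prop_kd / prop_ctrl if prop_ctrl > 0 else np.inf
    return float(p), float(fold), True


def usage_table(counts) -> pd.DataFrame:
    """Per-exon usage tests for both knockdowns plus the combiner verdict.

    ``counts`` is the long-format junction count table (exon_id, condition,
    replicate, inclusion, total); replicates are summed per condition, each
    knockdown is tested against control, and the conditional-thresholding
    combiner is applied to the two p-values and fold changes.
    """
    agg = counts.groupby(["exon_id", "condition"])[["inclusion", "total"]].sum()
    rows = []
    for exon_id in counts.exon_id.unique():
        incl_c, tot_c = agg.loc[(exon_id, "ctrl")]
        row = {"exon_id": exon_id}
        for kd in ("kd1", "kd2"):
            incl_k, tot_k = agg.loc[(exon_id, kd)]
            p, fold, testable = exon_usage_test(
                int(incl_k), int(tot_k), int(incl_c), int(tot_c)
            )
            row[f"p_{kd}"], row[f"fold_{kd}"], row[f"testable_{kd}"] = p, fold, testable
        row["significant"] = conditional_threshold(
            row["p_kd1"], row["p_kd2"], row["fold_kd1"], row["fold_kd2"]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def conditional_threshold(
    p_kd1: float, p_kd2: float, fold_kd1: float, fold_kd2: float
) -> bool:
    """Two-knockdown combiner: p < 0.01 in at least one knockdown and
    p < 0.05 in the second, with fold changes on the same side of 1."""
    same_side = (fold_kd1 - 1.0) * (fold_kd2 - 1.0) > 0
    return bool(
        min(p_kd1, p_kd2) < 0.01 and max(p_kd1, p_kd2) < 0.05 and same_side
    )


def categorize_alu_regulation(
    called: bool,
    fold_kd1: float,
    fold_kd2: float,
    total_reads: int,
) -> tuple[str, bool]:
    """Two-tier regulation category plus the established-exon flag.

    Upregulated Alu exons are those called by the combiner or showing a
    more than 2-fold increase in at least one knockdown.  Established
    exons carry at least 50 reads in total with fold changes below 1.5
    (in either direction) in both knockdowns.
    """
    folds = [f for f in (fold_kd1, fold_kd2) if np.isfinite(f)]
    max_fold = max(folds) if folds else np.nan
    min_fold = min(folds) if folds else np.nan
    if called and max_fold > 1:
        category = "up (called)"
    elif np.isfinite(max_fold) and max_fold > 2:
        category = "up (>2-fold)"
    elif (called and max_fold < 1) or (np.isfinite(min_fold) and min_fold < 0.5):
        category = "down"
    else:
        category = "unchanged"
    established = (
        total_reads >= 50
        and len(folds) == 2
        and all(max(f, 1.0 / f) < 1.5 for f in folds if f > 0)
    )
    return category, bool(established)
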