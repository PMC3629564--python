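"""File-format glue: FASTA, GTF, BED6 and TSV round-trips.

Genome sequences travel as plain ``dict[str, str]``; annotation GTFs are
read through :mod:`pyranges` and converted to :class:`~aluclip.core.GeneModel`
records.  Crosslink tracks use BED6 with one record per crosslinked
nucleotide and the score column holding the unique-event count.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AluRecord, BindingSite, CrosslinkTrack, GeneModel

BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- GTF --------------------------------------------------------------------

def _gtf_line(contig, source, feature, start, end, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    # GTF is 1-based inclusive
    return f"{contig}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}\n"


def write_gene_gtf(genes: list[GeneModel], path: str | Path, source: str = "aluclip") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = {"gene_id": g.gene_id, "gene_biotype": g.biotype}
            fh.write(_gtf_line(g.contig, source, "gene", g.start, g.end, g.strand, attrs))
            tx_attrs = {**attrs, "transcript_id": g.gene_id + ".t1"}
            for s, e in g.exons:
                fh.write(_gtf_line(g.contig, source, "exon", s, e, g.strand, tx_attrs))
            for s, e in g.utr5:
                fh.write(_gtf_line(g.contig, source, "five_prime_utr", s, e, g.strand, tx_attrs))
            for s, e in g.utr3:
                fh.write(_gtf_line(g.contig, source, "three_prime_utr", s, e, g.strand, tx_attrs))


def read_gene_gtf(path: str | Path) -> list[GeneModel]:
    df = pr.read_gtf(str(path)).df
    genes: dict[str, GeneModel] = {}
    for _, row in df[df.Feature == "gene"].iterrows():
        biotype = row.get("gene_biotype", "protein_coding")
        if not isinstance(biotype, str):
            biotype = "protein_coding"
        genes[row.gene_id] = GeneModel(
            gene_id=row.gene_id,
            contig=str(row.Chromosome),
            start=int(row.Start),
            end=int(row.End),
            strand=str(row.Strand),
            biotype=biotype,
        )
    feature_attr = {
        "exon": "exons",
        "five_prime_utr": "utr5",
        "three_prime_utr": "utr3",
    }
    for feature, attr in feature_attr.items():
        for _, row in df[df.Feature == feature].iterrows():
            getattr(genes[row.gene_id], attr).append((int(row.Start), int(row.End)))
    out = list(genes.values())
    for g in out:
        g.exons.sort()
        g.utr5.sort()
        g.utr3.sort()
    return out


def read_transcript_gtf(path: str | Path) -> list[dict]:
    """Read assembled-transcript exon predictions.

    Returns one record per transcript: ``{"transcript_id", "gene_id",
    "contig", "strand", "exons"}`` with exons sorted by coordinate.
    The ``gene_id`` is the assembler's own grouping (predicted gene model),
    not a reference gene.
    """
    df = pr.read_gtf(str(path)).df
    df = df[df.Feature == "exon"]
    out = []
    for (tx, gene), sub in df.groupby(["transcript_id", "gene_id"], observed=True):
        exons = sorted((int(s), int(e)) for s, e in zip(sub.Start, sub.End))
        out.append(
            {
                "transcript_id": tx,
                "gene_id": gene,
                "contig": str(sub.Chromosome.iloc[0]),
                "strand": str(sub.Strand.iloc[0]),
                "exons": exons,
            }
        )
    out.sort(key=lambda r: r["transcript_id"])
    return out


# -- BED6 -------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)


def write_track_bed(track: CrosslinkTrack, path: str | Path) -> None:
    rows = []
    for contig, strand in track.keys():
        for pos, n in sorted(track.counts(contig, strand).items()):
            rows.append((contig, pos, pos + 1, "xl", n, strand))
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_track_bed(path: str | Path) -> CrosslinkTrack:
    track = CrosslinkTrack()
    df = read_bed6(path)
    for row in df.itertuples(index=False):
        track.add(row.contig, row.strand, int(row.start), int(row.score))
    return track


def write_alu_bed(alus: list[AluRecord], path: str | Path) -> None:
    rows = [(a.contig, a.start, a.end, a.name, 0, a.strand) for a in alus]
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_alu_bed(path: str | Path) -> list[AluRecord]:
    df = read_bed6(path)
    return [
        AluRecord(name=str(r.name), contig=r.contig, start=int(r.start), end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]


# -- binding sites ----------------------------------------------------------

SITE_COLUMNS = [
    "contig", "start", "end", "strand", "summit", "event_count", "fdr", "gene_id",
]


def sites_to_frame(sites: list[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.contig, s.start, s.end, s.strand, s.summit, s.event_count, s.fdr, s.gene_id) for s in sites],
        columns=SITE_COLUMNS,
    )


def write_sites_tsv(sites: list[BindingSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[BindingSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        BindingSite(
            contig=str(r.contig), strand=r.strand, start=int(r.start), end=int(r.end),
            summit=int(r.summit), event_count=int(r.event_count), fdr=float(r.fdr),
            gene_id=str(r.gene_id),
        )
        for r in df.itertuples(index=False)
    ]
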