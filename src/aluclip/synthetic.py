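"""Synthetic iCLIP / RNA-seq data with planted RBP competition.

The generator emulates the statistical structure of a quantitative iCLIP
experiment on two proteins: a U-tract binder (hnRNP C-like) and a
polypyrimidine-tract binder (U2AF65-like) that is suppressed at U-tracts
occupied by the first protein.  A toy genome carries genes whose introns
host antisense Alu-like elements.  Each element follows the canonical Alu
anatomy — two arms separated by a poly(A) linker and followed by a poly(A)
tail — so that on the transcribed strand the element carries a linker
U-tract and an upstream U-tract followed by a mixed C/U polypyrimidine
tract ahead of the cryptic 3' splice site.

Crosslink counts are Poisson; exon inclusion follows a logistic link from
the U2AF65 rate at the upstream tract.  All randomness flows from a single
seed split into per-stage streams, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AluRecord, CrosslinkTrack, GeneModel, revcomp
from . import io as aio

BASES = np.array(list("ACGT"))

#: conditions simulated per protein
CONDITIONS = {"hnRNPC": ("ctrl", "kd"), "U2AF65": ("ctrl", "kd1", "kd2")}

_EXON_LEN = 200          # terminal exon length of the toy genes
_UTR_LEN = 100           # UTR portion of each terminal exon
_GENE_GAP = 500          # intergenic spacing
_PPT_LEN = 20            # mixed C/U polypyrimidine tract length
_ARM_LEN = 120           # Alu arm length
_PYR_WINDOW = 11         # window for the local pyrimidine score


def default_alu_consensus() -> tuple[str, dict[str, tuple[int, int]]]:
    """A synthetic ~290-nt Alu-like consensus and its landmark regions.

    Layout (consensus orientation): arm 1, poly(A) linker, arm 2, a
    purine-rich block (reverse complement of the transcribed-strand
    polypyrimidine tract) and the poly(A) tail.  Region names refer to the
    transcribed-strand role of each block: the tail reads as the *upstream*
    U-tract and the linker as the *linker* U-tract once the element sits
    antisense in a gene.
    """
    rng = np.random.default_rng(987123)
    arm1 = "".join(rng.choice(BASES, size=_ARM_LEN))
    arm2 = "".join(rng.choice(BASES, size=_ARM_LEN))
    # arm bases abutting the linker must not extend its transcribed U-tract
    if arm1.endswith("A"):
        arm1 = arm1[:-1] + "G"
    if arm2.startswith("A"):
        arm2 = "G" + arm2[1:]
    linker = "A" * 12
    # transcribed-strand PPT is ~60% U / 40% C; its first base is fixed to C
    # so the upstream U-tract stays a maximal run of its planted length
    ppt = "C" + "".join(rng.choice(["T", "C"], size=_PPT_LEN - 1, p=[0.6, 0.4]))
    tail = "A" * 14
    seq = arm1 + linker + arm2 + revcomp(ppt) + tail
    o = 0
    regions = {}
    for name, block in [
        ("arm1", arm1), ("linker_tract", linker), ("arm2", arm2),
        ("ppt", revcomp(ppt)), ("upstream_tract", tail),
    ]:
        regions[name] = (o, o + len(block))
        o += len(block)
    return seq, regions


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Rates are events per nucleotide; ``alpha`` is the hnRNP C affinity gain
    per uridine beyond the minimal 3-U tract, ``beta`` the U2AF65 rate at a
    pure-pyrimidine context, ``s`` the fraction of U2AF65 binding suppressed
    at hnRNP-C-occupied tracts in the control condition, and ``gamma`` the
    logistic slope linking the U2AF65 rate at the upstream tract to exon
    inclusion.
    """

    n_genes: int = 300
    gene_length_range: tuple[int, int] = (4000, 6000)
    n_alu_per_gene: int = 2
    exonized_per_gene: int = 1
    alu_consensus: str | None = None
    consensus_regions: dict[str, tuple[int, int]] | None = None
    utract_length_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (8.0, 2.0), "exonized": (10.0, 2.0)}
    )
    mutation_rate: float = 0.05
    base_rate_c: float = 0.01
    base_rate_u: float = 0.01
    alpha: float = 2.0
    beta: float = 2.0
    s: float = 0.8
    gamma: float = 8.0
    occ_threshold: float = 1.2
    depth: float = 500.0
    replicates: int = 2
    contig: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alu_consensus is None:
            self.alu_consensus, regions = default_alu_consensus()
            if self.consensus_regions is None:
                self.consensus_regions = regions
        if self.consensus_regions is None:
            raise ValueError("consensus_regions required with a custom consensus")
        for name in ("base_rate_c", "base_rate_u", "alpha", "beta", "mutation_rate", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("suppression factor s must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes < 1 or self.n_alu_per_gene < 0:
            raise ValueError("n_genes must be >= 1 and n_alu_per_gene >= 0")
        if not 0 <= self.exonized_per_gene <= self.n_alu_per_gene:
            raise ValueError("exonized_per_gene must be within [0, n_alu_per_gene]")
        lo, hi = self.gene_length_range
        if lo > hi or lo < 2 * _EXON_LEN + 1:
            raise ValueError("gene_length_range too small for the gene anatomy")


@dataclass
class SimTruth:
    """Planted parameters of a synthetic dataset.

    ``tracts`` has one row per U-tract (genomic interval, length, set label,
    occupancy rates per condition); ``exons`` one row per planted cryptic
    exon with its true inclusion levels.
    """

    tracts: pd.DataFrame
    exons: pd.DataFrame
    genes: list[GeneModel]
    alus: list[AluRecord]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_tract_len(rng, dist: tuple[float, float]) -> int:
    mean, sd = dist
    return int(np.clip(round(rng.normal(mean, sd)), 3, 14))


def _tx_to_genomic(a: int, elem_len: int, gene_strand: str, u: int, v: int) -> tuple[int, int]:
    """Map a transcript-orientation interval within an element to genomic."""
    if gene_strand == "+":
        return a + u, a + v
    return a + elem_len - v, a + elem_len - u


def generate_genome(config: SimConfig):
    """Build the toy genome with genes and planted antisense Alu elements.

    Returns ``(genome, genes, alus, truth)``; the truth tables carry the
    planted tract lengths, per-condition binding rates and true exon
    inclusion levels that downstream modules try to recover.
    """
    rng = _rng(config.seed, 0)
    cons = config.alu_consensus
    regions = config.consensus_regions
    a1s, a1e = regions["arm1"]
    lks, lke = regions["linker_tract"]
    a2s, a2e = regions["arm2"]
    ps, pe = regions["ppt"]
    ups, upe = regions["upstream_tract"]
    arm1, arm2, ppt_rc = cons[a1s:a1e], cons[a2s:a2e], cons[ps:pe]

    gene_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )
    total_len = int(gene_lengths.sum()) + _GENE_GAP * (config.n_genes + 1)
    seq = rng.choice(BASES, size=total_len)

    genes: list[GeneModel] = []
    alus: list[AluRecord] = []
    tract_rows: list[dict] = []
    exon_rows: list[dict] = []

    cursor = _GENE_GAP
    max_elem_len = len(arm1) + len(arm2) + len(ppt_rc) + 2 * 14
    for gi in range(config.n_genes):
        glen = int(gene_lengths[gi])
        gene_id = f"g{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        g0, g1 = cursor, cursor + glen
        cursor = g1 + _GENE_GAP
        intron0, intron1 = g0 + _EXON_LEN, g1 - _EXON_LEN
        needed = config.n_alu_per_gene * (max_elem_len + 100) + 100
        if intron1 - intron0 < needed:
            raise ValueError(
                f"gene {gene_id} (length {glen}) too short to host "
                f"{config.n_alu_per_gene} Alu element(s)"
            )
        if strand == "+":
            utr5 = [(g0, g0 + _UTR_LEN)]
            utr3 = [(g1 - _UTR_LEN, g1)]
        else:
            utr5 = [(g1 - _UTR_LEN, g1)]
            utr3 = [(g0, g0 + _UTR_LEN)]
        genes.append(
            GeneModel(
                gene_id=gene_id, contig=config.contig, start=g0, end=g1, strand=strand,
                exons=[(g0, g0 + _EXON_LEN), (g1 - _EXON_LEN, g1)], utr5=utr5, utr3=utr3,
            )
        )

        spacing = (intron1 - intron0) // max(config.n_alu_per_gene, 1)
        for ai in range(config.n_alu_per_gene):
            set_label = "exonized" if ai < config.exonized_per_gene else "control"
            dist = config.utract_length_distribution[set_label]
            l_up = _draw_tract_len(rng, dist)
            l_link = _draw_tract_len(rng, dist)

            # consensus-orientation element with planted tract lengths;
            # substitutions hit the arms only, so planted lengths stay exact
            def _mutate(s: str) -> str:
                if config.mutation_rate == 0:
                    return s
                arr = np.array(list(s))
                hits = np.nonzero(rng.random(len(s)) < config.mutation_rate)[0]
                for h in hits:
                    arr[h] = rng.choice(BASES[BASES != arr[h]])
                return "".join(arr)

            arm1m, arm2m = _mutate(arm1), _mutate(arm2)
            # keep the planted U-tracts maximal: arm bases abutting the
            # linker must not read as U on the transcribed strand
            if arm1m.endswith("A"):
                arm1m = arm1m[:-1] + "G"
            if arm2m.startswith("A"):
                arm2m = "G" + arm2m[1:]
            elem = arm1m + "A" * l_link + arm2m + ppt_rc + "A" * l_up
            elem_len = len(elem)
            a = intron0 + ai * spacing + 50
            if a + elem_len > intron1:
                raise ValueError(f"gene {gene_id} intron cannot fit Alu {ai}")
            alu_strand = "-" if strand == "+" else "+"
            # genomic plus-strand sequence of the element
            plus_seq = elem if alu_strand == "+" else revcomp(elem)
            seq[a : a + elem_len] = list(plus_seq)
            # sanitize the intronic base 5' of the upstream tract (transcript
            # orientation) so the planted run stays maximal
            if strand == "+":
                seq[a - 1] = "C"
            else:
                seq[a + elem_len] = "G"
            alu_name = f"{gene_id}_alu{ai}"
            alus.append(
                AluRecord(name=alu_name, contig=config.contig, start=a,
                          end=a + elem_len, strand=alu_strand, gene_id=gene_id)
            )

            # transcript-orientation layout of the element:
            # [upstream U-tract][PPT][rc(arm2)][linker U-tract][rc(arm1)]
            t_up = (0, l_up)
            t_ppt = (l_up, l_up + len(ppt_rc))
            t_exon = (t_ppt[1], t_ppt[1] + len(arm2))
            t_link = (t_exon[1], t_exon[1] + l_link)

            bound_up = config.alpha > 0 and l_up > 3
            bound_link = config.alpha > 0 and l_link > 3
            for kind, (u, v), length, bound in [
                ("upstream", t_up, l_up, bound_up),
                ("linker", t_link, l_link, bound_link),
            ]:
                gs, ge = _tx_to_genomic(a, elem_len, strand, u, v)
                lam_c = config.alpha * max(0, length - 3) / length
                lam_u_kd = config.beta
                lam_u_ctrl = config.beta * (1.0 - config.s * bound)
                tract_rows.append(
                    dict(
                        gene_id=gene_id, alu_name=alu_name, contig=config.contig,
                        start=gs, end=ge, strand=strand, kind=kind, length=length,
                        bound=bound, set_label=set_label, lambda_c=lam_c,
                        lambda_u_ctrl=lam_u_ctrl, lambda_u_kd=lam_u_kd,
                    )
                )

            if set_label == "exonized":
                lam_ctrl = config.beta * (1.0 - config.s * bound_up)
                lam_kd = config.beta
                psi_ctrl = _logistic(config.gamma * (lam_ctrl - config.occ_threshold))
                psi_kd = _logistic(config.gamma * (lam_kd - config.occ_threshold))
                regulated = bool(bound_up and (psi_kd - psi_ctrl) >= 0.1)
                es, ee = _tx_to_genomic(a, elem_len, strand, *t_exon)
                acceptor = es - 1 if strand == "+" else ee
                donor = ee if strand == "+" else es - 1
                exon_rows.append(
                    dict(
                        exon_id=f"{alu_name}_exon", gene_id=gene_id,
                        contig=config.contig, start=es, end=ee, strand=strand,
                        alu_name=alu_name, acceptor=acceptor, donor=donor,
                        psi_ctrl=psi_ctrl, psi_kd=psi_kd, regulated=regulated,
                    )
                )

    genome = {config.contig: "".join(seq)}
    truth = SimTruth(
        tracts=pd.DataFrame(tract_rows),
        exons=pd.DataFrame(exon_rows),
        genes=genes,
        alus=alus,
    )
    return genome, genes, alus, truth


def pyrimidine_score(tx_seq: str) -> np.ndarray:
    """Local pyrimidine score per position of a transcript-strand sequence.

    Fraction of C/T in a centred 11-nt window, rescaled so that the ~0.5
    background of random sequence maps to 0 and a pure pyrimidine context
    to 1.
    """
    is_pyr = np.frombuffer(tx_seq.encode(), dtype=np.uint8)
    is_pyr = ((is_pyr == ord("C")) | (is_pyr == ord("T"))).astype(float)
    half = _PYR_WINDOW // 2
    padded = np.pad(is_pyr, half, mode="edge")
    kernel = np.ones(_PYR_WINDOW) / _PYR_WINDOW
    frac = np.convolve(padded, kernel, mode="valid")
    return np.clip((frac - 0.5) / 0.5, 0.0, 1.0)


def _check_truth_genome(genome: dict[str, str], truth: SimTruth) -> None:
    for g in truth.genes:
        if g.contig not in genome or g.end > len(genome[g.contig]):
            raise ValueError(f"truth/genome mismatch: gene {g.gene_id} outside genome")
    if len(truth.tracts):
        for row in truth.tracts.itertuples(index=False):
            if row.contig not in genome or row.end > len(genome[row.contig]):
                raise ValueError("truth/genome mismatch: tract outside genome")


def generate_crosslink_tracks(
    genome: dict[str, str], truth: SimTruth, config: SimConfig
) -> dict[tuple[str, str], CrosslinkTrack]:
    """Poisson crosslink-event tracks per (protein, condition).

    Per transcript-orientation position p of each gene, the hnRNP C rate is
    ``base_rate_c`` plus ``alpha * max(0, L - 3) / L`` over each planted
    tract; the U2AF65 control rate is ``base_rate_u + beta * pyr(p) *
    (1 - s * bound(p))`` and the knockdown rate drops the suppression term.
    The hnRNP C knockdown track is background-only.
    """
    _check_truth_genome(genome, truth)
    rng = _rng(config.seed, 1)
    tracks = {
        (protein, cond): CrosslinkTrack()
        for protein, conds in CONDITIONS.items()
        for cond in conds
    }
    tracts_by_gene = (
        dict(tuple(truth.tracts.groupby("gene_id"))) if len(truth.tracts) else {}
    )
    for gene in sorted(truth.genes, key=lambda g: g.gene_id):
        plus = genome[gene.contig][gene.start : gene.end]
        tx_seq = plus if gene.strand == "+" else revcomp(plus)
        glen = len(tx_seq)
        score = pyrimidine_score(tx_seq)

        rate_c = np.full(glen, config.base_rate_c)
        suppressed = np.zeros(glen, dtype=bool)
        for row in tracts_by_gene.get(gene.gene_id, pd.DataFrame()).itertuples(index=False):
            if gene.strand == "+":
                u, v = row.start - gene.start, row.end - gene.start
            else:
                u, v = gene.end - row.end, gene.end - row.start
            rate_c[u:v] += config.alpha * max(0, row.length - 3) / row.length
            if row.bound:
                suppressed[u:v] = True

        rate_u_kd = config.base_rate_u + config.beta * score
        rate_u_ctrl = config.base_rate_u + config.beta * score * (
            1.0 - config.s * suppressed
        )
        per_track_rates = {
            ("hnRNPC", "ctrl"): rate_c,
            ("hnRNPC", "kd"): np.full(glen, config.base_rate_c),
            ("U2AF65", "ctrl"): rate_u_ctrl,
            ("U2AF65", "kd1"): rate_u_kd,
            ("U2AF65", "kd2"): rate_u_kd,
        }
        for key in sorted(per_track_rates):
            counts = rng.poisson(per_track_rates[key])
            for t_idx in np.nonzero(counts)[0]:
                gpos = (
                    gene.start + int(t_idx)
                    if gene.strand == "+"
                    else gene.end - 1 - int(t_idx)
                )
                tracks[key].add(gene.contig, gene.strand, gpos, int(counts[t_idx]))
    return tracks


def generate_expression_counts(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Junction-level inclusion/exclusion counts per exon, condition, replicate.

    Per exon and replicate the total junction depth is Poisson(``depth``)
    and the inclusion count Binomial(total, psi) with the condition's true
    inclusion level; both knockdowns share ``psi_kd``.  Per-gene totals are
    the sum of inclusion + exclusion over the gene's exons, so counts are
    conserved by construction.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(config.seed, 2)
    rows = []
    exons = truth.exons.sort_values("exon_id") if len(truth.exons) else truth.exons
    for row in exons.itertuples(index=False):
        for cond in ("ctrl", "kd1", "kd2"):
            psi = row.psi_ctrl if cond == "ctrl" else row.psi_kd
            for rep in range(1, config.replicates + 1):
                total = int(rng.poisson(config.depth))
                incl = int(rng.binomial(total, psi)) if total > 0 else 0
                rows.append(
                    dict(
                        exon_id=row.exon_id, gene_id=row.gene_id, condition=cond,
                        replicate=rep, inclusion=incl, exclusion=total - incl,
                        total=total,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["exon_id", "gene_id", "condition", "replicate",
                 "inclusion", "exclusion", "total"],
    )


def gene_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene junction totals per condition and replicate."""
    return (
        counts.groupby(["gene_id", "condition", "replicate"], as_index=False)["total"]
        .sum()
        .rename(columns={"total": "gene_total"})
    )


def simulate_dataset(config: SimConfig):
    """Run the full generator: genome, annotations, tracks and count tables."""
    genome, genes, alus, truth = generate_genome(config)
    tracks = generate_crosslink_tracks(genome, truth, config)
    counts = generate_expression_counts(truth, config)
    return genome, truth, tracks, counts


def write_dataset(config: SimConfig, outdir: str | Path) -> None:
    """Write the complete synthetic dataset as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, tracks, counts = simulate_dataset(config)
    aio.write_fasta(genome, outdir / "genome.fa")
    aio.write_gene_gtf(truth.genes, outdir / "genes.gtf")
    aio.write_alu_bed(truth.alus, outdir / "alu.bed")
    for (protein, cond), track in tracks.items():
        aio.write_track_bed(track, outdir / f"xl_{protein}_{cond}.bed")
    counts.to_csv(outdir / "exon_counts.tsv", sep="\t", index=False)
    truth.tracts.to_csv(outdir / "truth_tracts.tsv", sep="\t", index=False)
    truth.exons.to_csv(outdir / "truth_exons.tsv", sep="\t", index=False)
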