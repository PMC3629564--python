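"""Synthetic-data generator: determinism, planted structure, count laws."""

import numpy as np
import pandas as pd
import pytest

from aluclip.core import revcomp
from aluclip.synthetic import (
    SimConfig,
    default_alu_consensus,
    generate_crosslink_tracks,
    generate_expression_counts,
    generate_genome,
    gene_totals,
    pyrimidine_score,
)


def _cfg(**kw):
    base = dict(n_genes=4, gene_length_range=(4000, 4500), seed=5)
    base.update(kw)
    return SimConfig(**base)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        _cfg(s=1.5)
    with pytest.raises(ValueError):
        _cfg(alpha=-1)
    with pytest.raises(ValueError):
        _cfg(depth=0)
    with pytest.raises(ValueError):
        _cfg(exonized_per_gene=3, n_alu_per_gene=2)


def test_gene_too_short_raises_with_gene_name():
    with pytest.raises(ValueError, match="g0000"):
        generate_genome(_cfg(gene_length_range=(900, 901), n_alu_per_gene=2))


def test_zero_mutation_element_is_exact_consensus_revcomp():
    """With no substitutions and tract lengths forced to the consensus
    block lengths, the antisense element on the transcribed strand is
    exactly the reverse complement of the consensus."""
    cons, regions = default_alu_consensus()
    # rebuild a consensus whose poly(A) blocks are both 14 nt so a forced
    # draw of 14 reproduces it exactly
    a1s, a1e = regions["arm1"]
    a2s, a2e = regions["arm2"]
    ps, pe = regions["ppt"]
    cons14 = cons[a1s:a1e] + "A" * 14 + cons[a2s:a2e] + cons[ps:pe] + "A" * 14
    o, regions14 = 0, {}
    for name, ln in [("arm1", a1e - a1s), ("linker_tract", 14), ("arm2", a2e - a2s),
                     ("ppt", pe - ps), ("upstream_tract", 14)]:
        regions14[name] = (o, o + ln)
        o += ln
    cfg = _cfg(
        n_genes=1, n_alu_per_gene=1, exonized_per_gene=1, mutation_rate=0.0,
        alu_consensus=cons14, consensus_regions=regions14,
        utract_length_distribution={"control": (14.0, 0.0), "exonized": (14.0, 0.0)},
    )
    genome, genes, alus, truth = generate_genome(cfg)
    alu = alus[0]
    plus = genome[alu.contig][alu.start : alu.end]
    elem = plus if alu.strand == "+" else revcomp(plus)
    assert elem == cons14
    assert revcomp(plus if alu.strand == "-" else revcomp(plus)) == cons14


def test_determinism_same_seed_identical_outputs():
    a = generate_genome(_cfg(seed=9))
    b = generate_genome(_cfg(seed=9))
    assert a[0] == b[0]
    assert [(g.gene_id, g.start, g.end, g.strand) for g in a[1]] == [
        (g.gene_id, g.start, g.end, g.strand) for g in b[1]
    ]
    pd.testing.assert_frame_equal(a[3].tracts, b[3].tracts)
    ta = generate_crosslink_tracks(a[0], a[3], _cfg(seed=9))
    tb = generate_crosslink_tracks(b[0], b[3], _cfg(seed=9))
    assert all(ta[k] == tb[k] for k in ta)
    ca = generate_expression_counts(a[3], _cfg(seed=9))
    cb = generate_expression_counts(b[3], _cfg(seed=9))
    pd.testing.assert_frame_equal(ca, cb)


def test_forced_tract_lengths_appear_as_exact_u_runs():
    cfg = _cfg(
        n_genes=2, mutation_rate=0.0,
        utract_length_distribution={"control": (10.0, 0.0), "exonized": (10.0, 0.0)},
    )
    genome, genes, alus, truth = generate_genome(cfg)
    assert (truth.tracts.length == 10).all()
    for row in truth.tracts.itertuples(index=False):
        gene = next(g for g in truth.genes if g.gene_id == row.gene_id)
        plus = genome[row.contig][row.start : row.end]
        tx = plus if gene.strand == "+" else revcomp(plus)
        assert tx == "T" * 10
        # maximal: the transcript-strand neighbours are not U
        lo, hi = genome[row.contig][row.start - 1], genome[row.contig][row.end]
        if gene.strand == "+":
            assert lo != "T" and hi != "T"
        else:
            assert lo != "A" and hi != "A"


def test_annotations_mutually_consistent(tiny_genome):
    truth = tiny_genome["truth"]
    for alu in truth.alus:
        gene = next(g for g in truth.genes if g.gene_id == alu.gene_id)
        assert gene.start < alu.start and alu.end < gene.end
        assert alu.strand != gene.strand
    starts_ends = sorted((g.start, g.end) for g in truth.genes)
    for (s1, e1), (s2, e2) in zip(starts_ends, starts_ends[1:]):
        assert e1 <= s2       # genes non-overlapping


def test_truth_invariants(tiny_genome):
    tracts = tiny_genome["truth"].tracts
    exons = tiny_genome["truth"].exons
    assert (tracts.lambda_u_kd >= tracts.lambda_u_ctrl).all()
    reg = exons[exons.regulated]
    assert (reg.psi_kd > reg.psi_ctrl).all()
    assert ((exons.psi_kd - exons.psi_ctrl).abs() >= 0).all()


def test_suppression_limit_s1_background_only():
    """With s=1, the expected U2AF65 control count at a bound tract is
    background only."""
    cfg = _cfg(s=1.0, base_rate_u=0.0, seed=21)
    genome, genes, alus, truth = generate_genome(cfg)
    tracks = generate_crosslink_tracks(genome, truth, cfg)
    ctrl = tracks[("U2AF65", "ctrl")]
    bound = truth.tracts[truth.tracts.bound]
    total = sum(
        ctrl.events_in(r.contig, r.strand, r.start, r.end)
        for r in bound.itertuples(index=False)
    )
    assert total == 0


def test_alpha_zero_base_zero_hnrnpc_track_empty():
    cfg = _cfg(alpha=0.0, base_rate_c=0.0)
    genome, genes, alus, truth = generate_genome(cfg)
    tracks = generate_crosslink_tracks(genome, truth, cfg)
    assert tracks[("hnRNPC", "ctrl")].total() == 0
    assert not truth.tracts.bound.any()


def test_s0_control_equals_knockdown_in_expectation():
    """Monte-Carlo oracle: without suppression, mean U2AF65 counts at
    tracts agree between control and knockdown within sampling error."""
    cfg = SimConfig(
        n_genes=120, gene_length_range=(4000, 4500), n_alu_per_gene=1,
        s=0.0, seed=77,
    )
    genome, genes, alus, truth = generate_genome(cfg)
    tracks = generate_crosslink_tracks(genome, truth, cfg)
    ctrl, kd = tracks[("U2AF65", "ctrl")], tracks[("U2AF65", "kd1")]
    tracts = truth.tracts
    assert len(tracts) >= 200
    c = np.array([ctrl.events_in(r.contig, r.strand, r.start, r.end)
                  for r in tracts.itertuples(index=False)])
    k = np.array([kd.events_in(r.contig, r.strand, r.start, r.end)
                  for r in tracts.itertuples(index=False)])
    # Poisson means ~ beta * L per tract; relative MC error ~ 1/sqrt(sum)
    se = np.sqrt(c.mean() / len(c) + k.mean() / len(k))
    assert abs(c.mean() - k.mean()) < 4 * se


def test_truth_genome_mismatch_raises(tiny_genome):
    cfg = tiny_genome["config"]
    truth = tiny_genome["truth"]
    with pytest.raises(ValueError, match="mismatch"):
        generate_crosslink_tracks({"other": "ACGT" * 100}, truth, cfg)


def test_gamma_zero_gives_equal_psi():
    cfg = _cfg(gamma=0.0)
    _, _, _, truth = generate_genome(cfg)
    assert (truth.exons.psi_ctrl == truth.exons.psi_kd).all()
    assert (truth.exons.psi_ctrl == 0.5).all()


def test_psi_zero_gives_zero_inclusion():
    cfg = _cfg()
    _, _, _, truth = generate_genome(cfg)
    truth.exons["psi_ctrl"] = 0.0
    truth.exons["psi_kd"] = 0.0
    counts = generate_expression_counts(truth, cfg)
    assert (counts.inclusion == 0).all()
    assert (counts.exclusion == counts.total).all()


def test_count_conservation_per_gene():
    cfg = _cfg()
    _, _, _, truth = generate_genome(cfg)
    counts = generate_expression_counts(truth, cfg)
    assert (counts.inclusion + counts.exclusion == counts.total).all()
    totals = gene_totals(counts)
    merged = counts.groupby(["gene_id", "condition", "replicate"])["total"].sum()
    for row in totals.itertuples(index=False):
        assert merged[(row.gene_id, row.condition, row.replicate)] == row.gene_total


def test_delta_psi_recovery_simulation_oracle():
    """Planted inclusion change is recovered by the count-level estimate:
    mean estimated delta-psi over 50 replicated draws is within 0.05."""
    cfg = _cfg(depth=1000.0)
    _, _, _, truth = generate_genome(cfg)
    exon = truth.exons.iloc[[0]].copy()
    exon["psi_ctrl"], exon["psi_kd"] = 0.3, 0.7
    deltas = []
    for rep_seed in range(50):
        cfg_i = _cfg(depth=1000.0, seed=1000 + rep_seed)
        truth_i = type(truth)(tracts=truth.tracts, exons=exon, genes=truth.genes,
                              alus=truth.alus)
        counts = generate_expression_counts(truth_i, cfg_i)
        by_cond = counts.groupby("condition")[["inclusion", "total"]].sum()
        psi_hat = by_cond.inclusion / by_cond.total
        deltas.append(psi_hat["kd1"] - psi_hat["ctrl"])
    assert abs(np.mean(deltas) - 0.4) < 0.05


def test_pyrimidine_score_extremes():
    assert pyrimidine_score("T" * 30).max() == 1.0
    score = pyrimidine_score("A" * 30)
    assert (score == 0).all()


def test_monotonic_suppression_release_in_expectation():
    """The expected KD/Ctrl count ratio at a tract grows with the planted
    hnRNP C affinity (bound tracts released, unbound unchanged)."""
    cfg = _cfg(s=0.8, utract_length_distribution={"control": (5.0, 2.0),
                                                  "exonized": (5.0, 2.0)})
    _, _, _, truth = generate_genome(cfg)
    t = truth.tracts.sort_values("lambda_c")
    ratio = (t.lambda_u_kd / t.lambda_u_ctrl).to_numpy()
    assert t.bound.sum() > 0 and (~t.bound).sum() > 0
    assert np.all(np.diff(ratio) >= -1e-12)
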