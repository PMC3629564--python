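"""Exon filtering/merging, gene assignment, Alu classification, usage test."""

import logging

import numpy as np
import pytest

from aluclip.core import AluRecord, GeneModel
from aluclip.exons import (
    ExonRecord,
    JunctionTable,
    assign_gene,
    categorize_alu_regulation,
    classify_alu_exon,
    conditional_threshold,
    exon_usage_test,
    filter_exons,
    merge_exons,
    predict_disruption,
)

from oracles import fisher_two_sided, textbook_chi2_yates


def _tx(tx_id, exons, strand="+", contig="c"):
    return dict(transcript_id=tx_id, gene_id=tx_id + "_m", contig=contig,
                strand=strand, exons=exons)


def _junctions_for(transcripts):
    """Junction table supporting every internal splice site once."""
    j = {}
    for tx in transcripts:
        exons = tx["exons"]
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            key = (tx["contig"], tx["strand"], e1, s2)
            j[key] = j.get(key, 0) + 1
    return JunctionTable(j)


class TestFilterExons:
    def test_single_exon_transcript_dropped(self):
        txs = [_tx("t1", [(100, 400)])]
        assert filter_exons(txs, _junctions_for(txs)) == []

    def test_size_filters(self):
        """A 20-bp exon and a 10.5-kb exon are both dropped."""
        txs = [_tx("t1", [(100, 120), (200, 10_700), (11_000, 11_200)])]
        recs = filter_exons(txs, _junctions_for(txs))
        assert [(r.start, r.end) for r in recs] == [(11_000, 11_200)]

    def test_unsupported_exon_dropped(self):
        txs = [_tx("t1", [(100, 200), (300, 400)])]
        # junctions for a different contig: no support
        empty = JunctionTable({})
        assert filter_exons(txs, empty) == []

    def test_merging_outer_boundaries(self):
        """Overlapping exons [100,200) and [110,190) merge to [100,200)."""
        txs = [
            _tx("t1", [(100, 200), (300, 400)]),
            _tx("t2", [(110, 190), (300, 400)]),
        ]
        recs = filter_exons(txs, _junctions_for(txs))
        intervals = sorted((r.start, r.end) for r in recs)
        assert (100, 200) in intervals
        assert (110, 190) not in intervals
        merged = next(r for r in recs if (r.start, r.end) == (100, 200))
        assert merged.transcript_ids == {"t1", "t2"}

    def test_distant_boundaries_not_merged(self):
        """Overlapping exons whose starts differ by >= 25 bp stay separate."""
        txs = [
            _tx("t1", [(100, 200), (300, 400)]),
            _tx("t2", [(130, 210), (300, 400)]),
        ]
        recs = filter_exons(txs, _junctions_for(txs))
        intervals = sorted((r.start, r.end) for r in recs)
        assert (100, 200) in intervals and (130, 210) in intervals

    def test_unsorted_exons_raise(self):
        txs = [_tx("t1", [(300, 400), (100, 200)])]
        with pytest.raises(ValueError, match="unsorted"):
            filter_exons(txs, _junctions_for(txs))

    def test_filter_idempotent(self):
        txs = [
            _tx("t1", [(100, 200), (300, 400), (500, 900)]),
            _tx("t2", [(95, 205), (300, 400)]),
        ]
        recs = filter_exons(txs, _junctions_for(txs))
        again = merge_exons(recs)
        assert sorted((r.start, r.end) for r in again) == sorted(
            (r.start, r.end) for r in recs
        )

    def test_merge_order_independent(self):
        recs1 = [
            ExonRecord("c", 100, 200, "+", {"a"}, 1, 0),
            ExonRecord("c", 110, 195, "+", {"b"}, 1, 0),
            ExonRecord("c", 118, 210, "+", {"d"}, 1, 0),
        ]
        recs2 = list(reversed([ExonRecord(r.contig, r.start, r.end, r.strand,
                                          set(r.transcript_ids), 1, 0) for r in recs1]))
        out1 = sorted((r.start, r.end) for r in merge_exons(recs1))
        out2 = sorted((r.start, r.end) for r in merge_exons(recs2))
        assert out1 == out2 == [(100, 210)]


class TestAssignGene:
    genes = [
        GeneModel(gene_id="gA", contig="c", start=0, end=1000, strand="+"),
        GeneModel(gene_id="gB", contig="c", start=950, end=2000, strand="+"),
    ]

    def test_single_overlap_assigned(self):
        exon = ExonRecord("c", 100, 200, "+", {"t1"})
        assert assign_gene(exon, self.genes) == "gA"

    def test_multi_gene_overlap_discarded(self):
        exon = ExonRecord("c", 900, 1100, "+", {"t1"})
        assert assign_gene(exon, self.genes) is None
        assert exon.discard_reason == "overlaps multiple genes"

    def test_inherits_via_predicted_model(self):
        exon = ExonRecord("c", 3000, 3100, "+", {"t1"})
        models = {"m1": [(100, 200, "c", "+"), (3000, 3100, "c", "+")]}
        assert assign_gene(exon, self.genes, models, {"t1": "m1"}) == "gA"

    def test_unassignable_intergenic(self):
        exon = ExonRecord("c", 5000, 5100, "+", {"t1"})
        assert assign_gene(exon, self.genes) is None


class TestClassifyAluExon:
    alus = [AluRecord(name="alu1", contig="c", start=400, end=700, strand="-")]

    def test_supported_acceptor_in_antisense_alu(self):
        exon = ExonRecord("c", 500, 600, "+", acceptor_support=3, donor_support=1)
        assert classify_alu_exon(exon, self.alus, gene_strand="+")
        assert "acceptor" in exon.alu_splice_sites

    def test_sense_alu_does_not_count(self):
        exon = ExonRecord("c", 500, 600, "+", acceptor_support=3, donor_support=1)
        assert not classify_alu_exon(exon, self.alus, gene_strand="-")

    def test_unsupported_site_does_not_count(self):
        exon = ExonRecord("c", 500, 600, "+", acceptor_support=0, donor_support=0)
        assert not classify_alu_exon(exon, self.alus, gene_strand="+")

    def test_minus_strand_boundary_nucleotide(self):
        """On a minus-strand gene the acceptor is the intronic nucleotide
        just past the exon's high coordinate."""
        exon = ExonRecord("c", 100, 699, "-", acceptor_support=1)
        assert exon.splice_site("acceptor") == 699
        assert classify_alu_exon(exon, self.alus, gene_strand="-") is False  # alu sense
        alus_plus = [AluRecord(name="a", contig="c", start=400, end=700, strand="+")]
        assert classify_alu_exon(exon, alus_plus, gene_strand="-")


class TestPredictDisruption:
    def test_frameshift_by_length(self):
        fs, _, disrupted = predict_disruption(100, "A" * 100)
        assert fs and disrupted

    def test_stop_in_all_three_frames(self):
        seq = "TAAATAAATAAA"          # TAA tiled so each frame hits a stop
        fs, stops, disrupted = predict_disruption(len(seq), seq)
        assert not fs and stops == 3 and disrupted

    def test_clean_exon_not_disrupted(self):
        seq = "GCAGCCGCG" * 11     # length 99, no stops
        fs, stops, disrupted = predict_disruption(99, seq)
        assert not fs and stops == 0 and not disrupted

    def test_in_frame_no_stop_never_disrupted(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(10, 60)) * 3
            seq = "".join(rng.choice(["GCA", "GCC", "CTG", "AAC"], size=n // 3))
            fs, stops, disrupted = predict_disruption(n, seq)
            assert not disrupted

    def test_default_rule_logged(self, caplog):
        with caplog.at_level(logging.INFO, logger="aluclip.exons"):
            predict_disruption(99, "GCA" * 33)
        assert any("default combination rule" in m for m in caplog.messages)


class TestUsageTest:
    def test_identical_proportions_null(self):
        p, fold, testable = exon_usage_test(50, 500, 50, 500)
        assert testable and p > 0.9 and fold == pytest.approx(1.0)

    def test_matches_textbook_chi2(self):
        """[[5,95],[50,50]] has expected cells >= 5, so the Yates-corrected
        chi-square applies; p matches the hand formula."""
        p, _, _ = exon_usage_test(5, 100, 50, 100)
        assert p == pytest.approx(textbook_chi2_yates([[5, 95], [50, 50]]), rel=1e-9)

    def test_matches_fisher_when_cells_small(self):
        """Small expected cells switch to Fisher; p matches hypergeometric
        enumeration."""
        p, _, _ = exon_usage_test(1, 30, 8, 12)
        assert p == pytest.approx(fisher_two_sided([[1, 29], [8, 4]]), rel=1e-9)

    def test_zero_gene_total_untestable(self):
        p, fold, testable = exon_usage_test(0, 0, 5, 100)
        assert not testable and p == 1.0

    def test_all_zero_exon_untestable(self):
        p, _, testable = exon_usage_test(0, 100, 0, 100)
        assert not testable and p == 1.0


class TestConditionalThreshold:
    @pytest.mark.parametrize(
        "p1,p2,f1,f2,expected",
        [
            (0.005, 0.03, 2.0, 1.8, True),
            (0.02, 0.03, 2.0, 1.8, False),     # neither p < 0.01
            (0.005, 0.2, 2.0, 1.8, False),     # second not < 0.05
            (0.005, 0.03, 2.0, 0.5, False),    # discordant directions
            (0.005, 0.005, 0.4, 0.6, True),    # concordant down
        ],
    )
    def test_rule(self, p1, p2, f1, f2, expected):
        assert conditional_threshold(p1, p2, f1, f2) is expected


class TestCategorizeRegulation:
    def test_called_up(self):
        cat, est = categorize_alu_regulation(True, 3.0, 2.5, total_reads=40)
        assert cat == "up (called)" and not est

    def test_twofold_tier(self):
        cat, _ = categorize_alu_regulation(False, 2.5, 1.1, total_reads=40)
        assert cat == "up (>2-fold)"

    def test_established_flag(self):
        cat, est = categorize_alu_regulation(False, 1.2, 1.3, total_reads=60)
        assert cat == "unchanged" and est

    def test_not_established_below_reads(self):
        _, est = categorize_alu_regulation(False, 1.2, 1.3, total_reads=40)
        assert not est
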