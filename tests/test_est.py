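"""Poly-A tail detection, trimming, gene assignment and count matrices."""

import numpy as np
import pytest

from estmzt.core import STAGES, ValidationError
from estmzt.est import (
    AlignmentRecord,
    AssignmentThresholds,
    EstRecord,
    PolyATail,
    assign_all,
    assign_gene,
    build_count_matrix,
    detect_polya,
    reverse_complement,
    trim_polya,
)


class TestDetectPolya:
    def test_clean_terminal_tail(self):
        tail = detect_polya("GGCAATAAAGCTT" + "A" * 12, min_len=8, max_mismatch=0)
        assert (tail.start, tail.length, tail.mismatches) == (13, 12, 0)
        assert not tail.orientation_flipped

    def test_no_tail(self):
        assert detect_polya("ACGTACGTACGT") is None

    def test_one_interior_mismatch_allowed(self):
        tail = detect_polya("ACGT" + "AAAAAA" + "G" + "AAAAAAA", min_len=8, max_mismatch=1)
        assert (tail.length, tail.mismatches) == (14, 1)

    def test_mismatch_budget_limits_run(self):
        # with zero budget the run stops at the interior G
        tail = detect_polya("ACGT" + "AAAAAA" + "G" + "AAAAAAA", min_len=5, max_mismatch=0)
        assert (tail.length, tail.mismatches) == (7, 0)

    def test_leading_polyt_triggers_orientation_flip(self):
        body = "GGCATCGGATCCTAG"
        seq = "T" * 15 + reverse_complement(body)
        tail = detect_polya(seq, min_len=8, max_mismatch=1)
        assert tail.orientation_flipped
        assert tail.length >= 15

    def test_oriented_sequence_is_not_flipped(self):
        tail = detect_polya("CCGGT" + "A" * 20, min_len=8, max_mismatch=1)
        assert not tail.orientation_flipped

    def test_min_len_validation(self):
        with pytest.raises(ValidationError):
            detect_polya("AAAA", min_len=0)


class TestTrimPolya:
    def test_trim_arithmetic(self):
        seq = "C" * 40 + "A" * 20
        rec = EstRecord(id="e1", sequence=seq, stage="oocyte")
        tail = detect_polya(seq)
        trimmed, _ = trim_polya(rec, tail)
        assert len(trimmed) == len(seq) - tail.length == 40

    def test_roundtrip_exact_when_no_mismatches(self):
        seq = "GATTACAGGT" + "A" * 12
        rec = EstRecord(id="e2", sequence=seq, stage="blastula")
        tail = detect_polya(seq, max_mismatch=0)
        trimmed, tail = trim_polya(rec, tail)
        assert trimmed + "A" * tail.length == seq

    def test_tail_covering_whole_sequence_warns(self):
        rec = EstRecord(id="e3", sequence="A" * 30, stage="gastrula")
        tail = detect_polya(rec.sequence)
        with pytest.warns(UserWarning):
            trimmed, _ = trim_polya(rec, tail)
        assert trimmed == ""

    def test_inconsistent_tail_rejected(self):
        rec = EstRecord(id="e4", sequence="C" * 10 + "A" * 10, stage="oocyte")
        with pytest.raises(ValidationError):
            trim_polya(rec, PolyATail(start=3, length=10, mismatches=0))


class TestAssignGene:
    def test_gene_hit_above_threshold(self):
        rec = AlignmentRecord("e", "geneA", "gene", 0.80)
        out = assign_gene([rec])
        assert out.gene_id == "geneA" and out.rule == "gene_75"

    def test_exact_threshold_fails_strict_reading(self):
        assert assign_gene([AlignmentRecord("e", "geneA", "gene", 0.75)]) is None

    def test_contig_rule(self):
        rec = AlignmentRecord("e", "ctg1", "est_contig", 0.86, gene_id="geneB")
        out = assign_gene([rec])
        assert out.rule == "contig_85" and out.gene_id == "geneB"
        assert assign_gene([AlignmentRecord("e", "ctg1", "est_contig", 0.80)]) is None

    def test_downstream_distance_limit(self):
        near = AlignmentRecord("e", "geneA", "downstream", 0.80, downstream_distance=1500)
        far = AlignmentRecord("e", "geneB", "downstream", 0.90, downstream_distance=2500)
        out = assign_gene([near, far])
        assert out.gene_id == "geneA" and out.rule == "downstream_75"

    def test_highest_identity_wins(self):
        low = AlignmentRecord("e", "geneA", "gene", 0.80)
        high = AlignmentRecord("e", "geneB", "gene", 0.95)
        assert assign_gene([low, high]).gene_id == "geneB"

    def test_tie_breaks_on_span_then_name(self):
        short = AlignmentRecord("e", "geneB", "gene", 0.9, target_start=0, target_end=100)
        long = AlignmentRecord("e", "geneZ", "gene", 0.9, target_start=0, target_end=200)
        assert assign_gene([short, long]).gene_id == "geneZ"
        same1 = AlignmentRecord("e", "geneB", "gene", 0.9, target_start=0, target_end=100)
        # same gene through two equally good targets: smallest target id wins
        same2 = AlignmentRecord("e", "xctg", "gene", 0.9, target_start=0, target_end=100,
                                gene_id="geneB")
        assert assign_gene([same1, same2]).gene_id == "geneB"

    def test_ambiguous_between_distinct_genes_discarded(self):
        a = AlignmentRecord("e", "geneA", "gene", 0.9, target_start=0, target_end=100)
        b = AlignmentRecord("e", "geneB", "gene", 0.9, target_start=0, target_end=100)
        assert assign_gene([a, b]) is None

    def test_mixed_est_ids_rejected(self):
        with pytest.raises(ValidationError):
            assign_gene(
                [AlignmentRecord("e1", "g", "gene", 0.9), AlignmentRecord("e2", "g", "gene", 0.9)]
            )

    def test_inclusive_thresholds_config(self):
        thresholds = AssignmentThresholds(strict=False)
        out = assign_gene([AlignmentRecord("e", "geneA", "gene", 0.75)], thresholds)
        assert out is not None


def test_assign_all_records_discard_reasons():
    by_est = {
        "hit": [AlignmentRecord("hit", "geneA", "gene", 0.9)],
        "weak": [AlignmentRecord("weak", "geneA", "gene", 0.5)],
        "tied": [
            AlignmentRecord("tied", "geneA", "gene", 0.9),
            AlignmentRecord("tied", "geneB", "gene", 0.9),
        ],
    }
    assignments, discards = assign_all(by_est, ["hit", "weak", "tied", "lost"])
    assert set(assignments) == {"hit"}
    reasons = dict(zip(discards["est_id"], discards["reason"]))
    assert reasons == {"weak": "no_qualifying_hit", "tied": "ambiguous", "lost": "no_hit"}


class TestCountMatrix:
    def _records(self, spec):
        return [
            EstRecord(id=f"e{i}", sequence="ACGT", stage=stage)
            for i, stage in enumerate(spec)
        ]

    def test_tally(self):
        from estmzt.est import GeneAssignment

        records = self._records(["oocyte", "oocyte", "blastula", "blastula", "gastrula"])
        assignments = [
            GeneAssignment(est_id=r.id, gene_id="geneA", rule="gene_75", identity=0.9)
            for r in records
        ]
        matrix, recon = build_count_matrix(assignments, records)
        assert matrix.counts.loc["geneA"].tolist() == [2, 0, 2, 1]
        assert (recon["assigned"] + recon["discarded"]).tolist() == recon["total"].tolist()

    def test_zero_assignments(self):
        records = self._records(["oocyte", "gastrula"])
        matrix, recon = build_count_matrix([], records)
        assert matrix.counts.empty
        assert recon["discarded"].sum() == 2

    def test_duplicate_est_id_rejected(self):
        records = [
            EstRecord(id="dup", sequence="ACGT", stage="oocyte"),
            EstRecord(id="dup", sequence="ACGT", stage="oocyte"),
        ]
        with pytest.raises(ValidationError):
            build_count_matrix([], records)


class TestSyntheticRoundTrip:
    """With error_rate=0 the pipeline must recover the truth exactly."""

    def test_all_tails_detected_and_counts_exact(self, exact_dataset, exact_result):
        truth_counts = exact_dataset.truth.counts
        observed = exact_result.matrix.counts.reindex(truth_counts.index, fill_value=0)
        assert (observed.values == truth_counts.values).all()
        assert len(exact_result.discards) == 0

    def test_per_stage_conservation(self, exact_dataset, exact_result):
        recon = exact_result.reconciliation
        for k, stage in enumerate(STAGES):
            row = recon[recon["stage"] == stage].iloc[0]
            assert row["assigned"] + row["discarded"] == row["total"]
            assert row["total"] == exact_dataset.config.library_sizes[k]
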