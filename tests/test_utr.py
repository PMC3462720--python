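"""Cleavage-site inference, isoform clustering and UTR length statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estmzt.core import ValidationError
from estmzt.est import GeneAssignment, PolyATail
from estmzt.utr import (
    CleavageSite,
    GeneModel,
    UtrRecord,
    cluster_isoforms,
    compute_utr_length,
    infer_cleavage_site,
    length_difference_test,
    utr_length_summary,
)

MODEL = GeneModel(gene_id="g1", contig="c1", strand="+", cds_end=100)
ASSIGN = GeneAssignment(est_id="e1", gene_id="g1", rule="gene_75", identity=0.99)
TAIL = PolyATail(start=200, length=20, mismatches=0)


class TestInferCleavageSite:
    def test_direct_mapping(self):
        site, reason = infer_cleavage_site(ASSIGN, 287, TAIL, MODEL)
        assert reason is None and site.position == 287

    def test_upstream_of_stop_discarded(self):
        site, reason = infer_cleavage_site(ASSIGN, 90, TAIL, MODEL)
        assert site is None and reason == "upstream_of_stop"

    def test_gene_mismatch_rejected(self):
        other = GeneModel(gene_id="g2", contig="c1", strand="+", cds_end=100)
        with pytest.raises(ValidationError):
            infer_cleavage_site(ASSIGN, 287, TAIL, other)


class TestUtrLength:
    @pytest.mark.parametrize(
        "cds_end, position, expected",
        [(100, 176, 76), (100, 100, 0), (150, 337, 187)],
    )
    def test_arithmetic(self, cds_end, position, expected):
        model = GeneModel(gene_id="g", contig="c", strand="+", cds_end=cds_end)
        site = CleavageSite(gene_id="g", position=position)
        assert compute_utr_length(model, site) == expected

    def test_upstream_site_rejected(self):
        site = CleavageSite(gene_id="g1", position=90)
        with pytest.raises(ValidationError):
            compute_utr_length(MODEL, site)

    @given(
        cds_end=st.integers(0, 10_000),
        length=st.integers(0, 5_000),
        shift=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_translation_invariance(self, cds_end, length, shift):
        base = compute_utr_length(
            GeneModel(gene_id="g", contig="c", strand="+", cds_end=cds_end),
            CleavageSite(gene_id="g", position=cds_end + length),
        )
        shifted = compute_utr_length(
            GeneModel(gene_id="g", contig="c", strand="+", cds_end=cds_end + shift),
            CleavageSite(gene_id="g", position=cds_end + shift + length),
        )
        assert base == shifted == length


def sites(positions, gene_id="g"):
    return [CleavageSite(gene_id=gene_id, position=p) for p in positions]


class TestClusterIsoforms:
    def test_two_clusters(self):
        isoforms = cluster_isoforms(sites([500, 505, 630]), tolerance=10)
        assert [i.position for i in isoforms] == [503, 630]
        assert [i.support for i in isoforms] == [2, 1]

    def test_single_site(self):
        isoforms = cluster_isoforms(sites([500]))
        assert len(isoforms) == 1 and isoforms[0].support == 1

    def test_single_linkage_chaining(self):
        assert len(cluster_isoforms(sites([500, 509, 518]), tolerance=10)) == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        positions = rng.integers(0, 2000, size=30).tolist()
        ref = cluster_isoforms(sites(positions), tolerance=15)
        for _ in range(5):
            rng.shuffle(positions)
            perm = cluster_isoforms(sites(positions), tolerance=15)
            assert [(i.position, i.support) for i in perm] == [
                (i.position, i.support) for i in ref
            ]

    def test_idempotent_on_isoform_positions(self):
        isoforms = cluster_isoforms(sites([100, 104, 300, 302, 700]), tolerance=10)
        again = cluster_isoforms(
            [CleavageSite(gene_id="g", position=i.position, support=i.support)
             for i in isoforms],
            tolerance=10,
        )
        assert [(i.position, i.support) for i in again] == [
            (i.position, i.support) for i in isoforms
        ]

    def test_support_conserved(self):
        positions = [10, 12, 14, 200, 203, 500]
        isoforms = cluster_isoforms(sites(positions), tolerance=5)
        assert sum(i.support for i in isoforms) == len(positions)

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValidationError):
            cluster_isoforms(sites([1]) + sites([2], gene_id="other"))


class TestLengthSummary:
    def test_mean_and_sem(self):
        records = [UtrRecord(gene_id="g", isoform_index=i, length=n)
                   for i, n in enumerate([10, 20, 30])]
        row = utr_length_summary(records).iloc[0]
        assert row["mean_length"] == pytest.approx(20.0)
        assert row["sem"] == pytest.approx(5.7735, abs=1e-3)

    def test_single_record_sem_undefined(self):
        row = utr_length_summary([UtrRecord(gene_id="g", isoform_index=0, length=42)]).iloc[0]
        assert row["mean_length"] == 42
        assert np.isnan(row["sem"])

    def test_empty_classes_absent(self):
        records = [UtrRecord(gene_id="g", isoform_index=0, length=5,
                             transcript_class="degrading")]
        table = utr_length_summary(records)
        assert table["class"].tolist() == ["degrading"]


class TestLengthDifference:
    def test_omnibus_matches_rank_oracle(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        result = length_difference_test(groups)
        assert result["kruskal_wallis"].statistic == pytest.approx(7.2)
        assert result["dunn"] is not None  # p = 0.027 <= 0.05

    def test_identical_groups_no_posthoc(self):
        result = length_difference_test({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert result["kruskal_wallis"].statistic == 0.0
        assert result["dunn"] is None

    def test_normality_reported_before_nonparametric_path(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(size=30).tolist(), "b": rng.normal(1, size=30).tolist()}
        result = length_difference_test(groups)
        assert result["normality"]["a"].method == "dagostino_pearson"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            length_difference_test({"a": [1.0], "b": []})


class TestSyntheticSiteRecovery:
    def test_error_free_sites_match_truth_exactly(self, exact_dataset, exact_result):
        truth_sites = {
            gene_id: {int(s) for s in row["sites"].split(",")}
            for gene_id, row in exact_dataset.truth.genes.iterrows()
        }
        assert exact_result.isoforms_by_gene  # something was recovered
        for gene_id, isoforms in exact_result.isoforms_by_gene.items():
            for iso in isoforms:
                assert iso.position in truth_sites[gene_id]

    def test_mito_genes_excluded_from_utr_records(self, exact_dataset, exact_result):
        mito = {g for g, m in exact_dataset.models.items() if m.is_mito}
        assert mito  # fixture has mitochondrial genes
        assert all(rec.gene_id not in mito for rec in exact_result.utr_records)
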