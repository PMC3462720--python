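"""Ground-truth generator: determinism, conservation, constraint satisfaction."""

import numpy as np
import pandas as pd
import pytest

from estmzt.core import STAGES, ValidationError
from estmzt.simulate import (
    SimConfig,
    generate_gene_models,
    sample_counts,
    simulate_dataset,
    simulate_stage_profiles,
    synthesize_ests,
    synthesize_qpcr,
)

SMALL = dict(n_genes=20, n_mito_genes=3, library_sizes=(100, 100, 100, 100))


class TestConfigValidation:
    def test_error_names_offending_field(self):
        with pytest.raises(ValidationError, match="error_rate"):
            SimConfig(error_rate=0.5)
        with pytest.raises(ValidationError, match="class_mixture"):
            SimConfig(class_mixture={"degrading": 1.0, "stable": 0.5,
                                     "activating": 0.0, "unclassified": 0.0})
        with pytest.raises(ValidationError, match="n_mito_genes"):
            SimConfig(n_genes=5, n_mito_genes=6)
        with pytest.raises(ValidationError, match="library_sizes"):
            SimConfig(library_sizes=(0, 10, 10, 10))


class TestGeneModels:
    def test_counts_forced_by_config(self):
        config = SimConfig(n_genes=10, n_mito_genes=2, seed=1)
        _, models, truth = generate_gene_models(config)
        assert len(models) == 10
        assert int(truth.genes["is_mito"].sum()) == 2

    def test_determinism(self):
        config = SimConfig(**SMALL, seed=7)
        ds1 = simulate_dataset(config)
        ds2 = simulate_dataset(SimConfig(**SMALL, seed=7))
        assert ds1.genome == ds2.genome
        assert [(r.id, r.sequence) for r in ds1.ests] == [
            (r.id, r.sequence) for r in ds2.ests
        ]
        pd.testing.assert_frame_equal(ds1.truth.genes, ds2.truth.genes)
        pd.testing.assert_frame_equal(ds1.truth.counts, ds2.truth.counts)

    def test_seed_changes_output(self):
        ds1 = simulate_dataset(SimConfig(**SMALL, seed=1))
        ds2 = simulate_dataset(SimConfig(**SMALL, seed=2))
        assert ds1.genome != ds2.genome

    def test_isoform_prob_one_gives_two_sites_everywhere(self):
        config = SimConfig(
            **SMALL,
            isoform_prob={c: 1.0 for c in ("degrading", "stable", "activating", "unclassified")},
            seed=3,
        )
        _, _, truth = generate_gene_models(config)
        assert (truth.genes["n_isoforms"] >= 2).all()

    def test_sites_downstream_of_cds_and_well_separated(self):
        config = SimConfig(**SMALL, seed=5)
        _, models, truth = generate_gene_models(config)
        for gene_id, row in truth.genes.iterrows():
            sites = [int(s) for s in row["sites"].split(",")]
            assert all(s >= models[gene_id].cds_end + config.min_utr_len for s in sites)
            gaps = np.diff(sites)
            assert (gaps >= config.min_site_gap).all()


class TestStageProfiles:
    def test_labelled_classes_satisfy_their_strict_rule(self):
        """Hand-coded rule check on the true proportions (independent of the
        generator's own rejection test)."""
        config = SimConfig(n_genes=120, n_mito_genes=5, seed=9)
        _, _, truth = generate_gene_models(config)
        truth = simulate_stage_profiles(config, truth)
        for gene_id, row in truth.genes.iterrows():
            p = [row[f"p_{s}"] for s in STAGES]
            assert abs(sum(p) - 1.0) < 1e-9
            cls = row["transcript_class"]
            if cls == "degrading":
                assert p[0] + p[1] + p[2] >= 0.95
                assert p[3] <= 0.05
            elif cls == "activating":
                assert p[2] + p[3] >= 0.95
            elif cls == "stable":
                assert min(p) >= 0.10 and max(p) <= 0.40

    def test_flat_dirichlet_mean_for_unclassified(self):
        mixture = {"degrading": 0.0, "stable": 0.0, "activating": 0.0, "unclassified": 1.0}
        config = SimConfig(n_genes=1000, n_mito_genes=0, class_mixture=mixture, seed=13)
        _, _, truth = generate_gene_models(config)
        truth = simulate_stage_profiles(config, truth)
        # flat Dirichlet: mean 0.25 per stage, var = 3/80, SE = sqrt(var/n)
        se = np.sqrt(3.0 / 80.0 / 1000)
        for stage in STAGES:
            assert abs(truth.genes[f"p_{stage}"].mean() - 0.25) <= 3 * se


class TestCounts:
    def test_per_stage_totals_equal_library_sizes(self):
        config = SimConfig(**SMALL, seed=17)
        _, _, truth = generate_gene_models(config)
        truth = sample_counts(config, simulate_stage_profiles(config, truth))
        for k, stage in enumerate(STAGES):
            assert truth.counts[stage].sum() == config.library_sizes[k]

    def test_single_stage_gene_yields_single_stage_ests(self):
        config = SimConfig(n_genes=1, n_mito_genes=0, library_sizes=(50, 10, 10, 10), seed=2)
        _, models, truth = generate_gene_models(config)
        truth = simulate_stage_profiles(config, truth)
        for stage in STAGES:  # degenerate profile: everything in the oocyte
            truth.genes[f"p_{stage}"] = 1.0 if stage == "oocyte" else 0.0
        truth = sample_counts(config, truth)
        ests = synthesize_ests(config, models, truth)
        assert len(ests) == 50
        assert all(rec.stage == "oocyte" for rec in ests)


class TestEstSynthesis:
    def test_error_free_reads_are_exact_substrings_plus_tail(self):
        config = SimConfig(**SMALL, error_rate=0.0, seed=19)
        ds = simulate_dataset(config)
        lo, hi = config.polya_len_params
        for rec in ds.ests[:200]:
            gene_id, stage, _ = rec.id.split("|")
            assert rec.stage == stage
            body = rec.sequence.rstrip("A")
            tail_len = len(rec.sequence) - len(body)
            assert lo <= tail_len  # forced non-A bases bound the tail below
            assert body in (ds.models[gene_id].transcript_seq or "")

    def test_library_sizes_respected(self):
        config = SimConfig(**SMALL, seed=23)
        ds = simulate_dataset(config)
        per_stage = {s: 0 for s in STAGES}
        for rec in ds.ests:
            per_stage[rec.stage] += 1
        assert [per_stage[s] for s in STAGES] == list(config.library_sizes)

    def test_inserted_motifs_present_in_utr_sequences(self):
        """The scanned motif content of each isoform's UTR equals the truth."""
        from estmzt.motifs import DEFAULT_CATALOGUE, scan_motifs

        config = SimConfig(**SMALL, seed=29)
        _, models, truth = generate_gene_models(config)
        for gene_id, row in truth.genes.iterrows():
            inserted = set(filter(None, row["motifs"].split(",")))
            transcript = models[gene_id].transcript_seq or ""
            cds_end = models[gene_id].cds_end
            for site in (int(s) for s in row["sites"].split(",")):
                profile = scan_motifs(transcript[cds_end:site], DEFAULT_CATALOGUE)
                present = {m for m, flag in profile.presence.items() if flag}
                assert present == inserted, gene_id


def test_synthetic_qpcr_table_shape():
    config = SimConfig(n_genes=5, n_mito_genes=0, seed=31)
    _, _, truth = generate_gene_models(config)
    truth = simulate_stage_profiles(config, truth)
    rng = np.random.default_rng(1)
    table = synthesize_qpcr(truth, truth.genes.index.tolist(), rng, n_replicates=3)
    assert set(table["gene_id"]) == set(truth.genes.index) | {"hba_spike"}
    assert (table["ct"] > 0).all()
    assert len(table) == (5 + 1) * 4 * 3
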