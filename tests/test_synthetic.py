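"""Generator contracts: planted structure must be recoverable by construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oralmgx import synthetic
from oralmgx.synthetic import CARIES, HEALTHY, CommunitySpec


class TestReferenceSet:
    def test_shared_segment_is_byte_identical_between_genomes(self, small_spec):
        ref = synthetic.generate_reference_set(small_spec)
        a, b = ref.genomes["sp000"], ref.genomes["sp001"]
        assert len(a) == len(b) == 1000
        # the 100 bp segment occurs verbatim in both genomes
        shared = [a[i : i + 100] for i in range(901)]
        assert any(seg in b for seg in shared)

    def test_same_seed_reproduces_identical_output(self, small_spec):
        r1 = synthetic.generate_reference_set(small_spec)
        r2 = synthetic.generate_reference_set(small_spec)
        assert r1.genomes == r2.genomes
        pd.testing.assert_frame_equal(r1.genes, r2.genes)

    def test_oversized_shared_segment_rejected(self):
        spec = CommunitySpec(
            n_species=2, genome_length=1000, shared_segments=[("sp000", "sp001", 2000)]
        )
        with pytest.raises(ValueError, match="does not fit"):
            synthetic.generate_reference_set(spec)

    def test_genes_tile_each_genome_without_overlap(self, small_spec):
        ref = synthetic.generate_reference_set(small_spec, gene_length=200)
        for sid, sub in ref.genes.groupby("species_id"):
            sub = sub.sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == 1000
            assert (sub["end"].iloc[:-1].to_numpy() == sub["start"].iloc[1:].to_numpy()).all()


class TestSampleReads:
    def test_species_counts_follow_binomial_expectation(self):
        spec = CommunitySpec(n_species=2, genome_length=2000, seed=5)
        ref = synthetic.generate_reference_set(spec)
        pairs, _ = synthetic.generate_sample_reads(
            ref.genomes, {"sp000": 0.8, "sp001": 0.2}, n_reads=100000, seed=5
        )
        # equal-length genomes: reads ~ Binomial(n, 0.8); check within 3 s.d.
        from oralmgx.qc import ExactReferenceAligner, classify_alignments

        partition = classify_alignments(ExactReferenceAligner(ref.genomes, 100).align(pairs))
        counts = pd.Series(list(partition.unique.values())).value_counts()
        sd = np.sqrt(100000 * 0.8 * 0.2)
        assert abs(counts["sp000"] - 80000) < 3 * sd

    def test_host_fraction_one_marks_every_read(self):
        spec = CommunitySpec(n_species=2, genome_length=2000, seed=5)
        ref = synthetic.generate_reference_set(spec)
        host = synthetic.generate_host_genome(5000, seed=1)
        pairs, host_ids = synthetic.generate_sample_reads(
            ref.genomes, {"sp000": 0.5, "sp001": 0.5}, n_reads=200,
            host_genome=host, host_fraction=1.0, seed=5,
        )
        assert {p.id for p in pairs} == host_ids

    def test_fixed_seed_gives_identical_reads(self):
        spec = CommunitySpec(n_species=2, genome_length=2000, seed=5)
        ref = synthetic.generate_reference_set(spec)
        args = (ref.genomes, {"sp000": 0.5, "sp001": 0.5}, 50)
        p1, _ = synthetic.generate_sample_reads(*args, seed=9)
        p2, _ = synthetic.generate_sample_reads(*args, seed=9)
        assert [(p.id, p.bases_1, p.bases_2) for p in p1] == [
            (p.id, p.bases_1, p.bases_2) for p in p2
        ]

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            synthetic.generate_sample_reads({}, {}, 10)


class TestAbundanceMatrix:
    def test_mgs_genes_are_perfectly_rank_correlated_at_zero_noise(self):
        spec = CommunitySpec(n_species=5, n_samples_per_group=10,
                             mgs_spec=[(30, "sp000")], seed=2)
        data, truth = synthetic.generate_abundance_matrix(
            spec, level="gene", noise_sd=0.0, n_background_genes=5
        )
        members = [g for g, m in truth.true_mgs_membership.items() if m == "mgs00"]
        assert len(members) == 30
        block = data.relative.loc[members].to_numpy()
        for row in block[1:]:
            assert spearmanr(block[0], row).statistic == pytest.approx(1.0)

    def test_differential_effect_ratio_exact_when_variation_off(self):
        spec = CommunitySpec(n_species=5, n_samples_per_group=6,
                             differential_species=[("sp001", 2.0, CARIES)], seed=3)
        data, _ = synthetic.generate_abundance_matrix(
            spec, level="species", noise_sd=0.0, profile_sd=0.0
        )
        caries = data.labels.index[data.labels == CARIES]
        healthy = data.labels.index[data.labels == HEALTHY]
        row = data.raw.loc["sp001"]
        assert row[caries].mean() / row[healthy].mean() == pytest.approx(4.0, abs=1e-12)

    def test_columns_sum_to_one(self):
        spec = CommunitySpec(n_species=30, n_samples_per_group=8, seed=4)
        data, truth = synthetic.generate_abundance_matrix(spec, level="species")
        np.testing.assert_allclose(data.relative.sum(axis=0), 1.0, atol=1e-9)
        truth.validate()

    def test_planted_edge_shares_rank_order_at_zero_noise(self):
        spec = CommunitySpec(n_species=10, n_samples_per_group=10,
                             planted_edges=[("sp004", "sp007", 1)], seed=6)
        data, _ = synthetic.generate_abundance_matrix(spec, level="species", noise_sd=0.0)
        rho = spearmanr(data.relative.loc["sp004"], data.relative.loc["sp007"]).statistic
        assert rho == pytest.approx(1.0)

    def test_negative_edge_anticorrelated_on_raw_scale(self):
        spec = CommunitySpec(n_species=10, n_samples_per_group=10,
                             planted_edges=[("sp004", "sp007", -1)], seed=6)
        data, _ = synthetic.generate_abundance_matrix(spec, level="species", noise_sd=0.0)
        rho = spearmanr(data.raw.loc["sp004"], data.raw.loc["sp007"]).statistic
        assert rho == pytest.approx(-1.0)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            synthetic.generate_abundance_matrix(CommunitySpec(), level="strain")


class TestMetadata:
    def test_caries_children_have_severe_dmfs_and_healthy_zero(self):
        labels = [CARIES] * 10 + [HEALTHY] * 8
        table = synthetic.generate_metadata(18, labels, seed=0)
        assert (table.loc[table["group"] == HEALTHY, "dmfs"] == 0).all()
        assert (table.loc[table["group"] == CARIES, "dmfs"] >= 8).all()

    def test_ages_span_preschool_range(self):
        table = synthetic.generate_metadata(200, [CARIES] * 200, seed=1)
        assert table["age"].between(45, 73).all()

    def test_fixed_seed_reproduces_table(self):
        labels = [CARIES, HEALTHY] * 5
        t1 = synthetic.generate_metadata(10, labels, seed=3)
        t2 = synthetic.generate_metadata(10, labels, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


def test_spec_validation_rejects_bad_fields():
    with pytest.raises(ValueError):
        CommunitySpec(host_fraction=1.5).validate()
    with pytest.raises(ValueError):
        CommunitySpec(n_species=2, shared_segments=[("sp000", "sp000", 10)]).validate()
    with pytest.raises(ValueError):
        CommunitySpec(differential_species=[("sp000", np.inf, CARIES)]).validate()
    with pytest.raises(ValueError):
        CommunitySpec(mgs_spec=[(0, "sp000")]).validate()
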