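"""Diversity, Bray-Curtis, PCoA and permutation tests, with independent
cross-checks against scikit-bio's implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from oralmgx import community


def random_distance(rng, n):
    points = rng.normal(size=(n, 3))
    return pd.DataFrame(squareform(pdist(points)))


class TestAlphaDiversity:
    def test_uniform_community_closed_forms(self):
        res = community.alpha_diversity([0.25, 0.25, 0.25, 0.25])
        assert res["shannon"] == pytest.approx(np.log(4), abs=1e-9)
        assert res["simpson"] == pytest.approx(0.75, abs=1e-9)
        assert res["richness"] == 4

    def test_single_species_degenerate(self):
        res = community.alpha_diversity([1.0, 0.0])
        assert res == {"richness": 1, "shannon": 0.0, "simpson": 0.0}

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(20))
        a = community.alpha_diversity(p)
        b = community.alpha_diversity(p[::-1])
        assert a == pytest.approx(b)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            community.alpha_diversity([0.0, 0.0])


class TestBrayCurtis:
    def test_disjoint_supports_give_one(self):
        d = community.bray_curtis(pd.DataFrame({"x": [1, 0], "y": [0, 1]}))
        assert d.loc["x", "y"] == pytest.approx(1.0)

    def test_identical_samples_give_zero(self):
        d = community.bray_curtis(pd.DataFrame({"x": [1, 2], "y": [1, 2]}))
        assert d.loc["x", "y"] == pytest.approx(0.0)

    def test_hand_value(self):
        d = community.bray_curtis(pd.DataFrame({"x": [2, 1], "y": [1, 1]}))
        assert d.loc["x", "y"] == pytest.approx(0.2, abs=1e-9)

    def test_all_zero_sample_flagged(self):
        with pytest.raises(ValueError):
            community.bray_curtis(pd.DataFrame({"x": [0, 0], "y": [1, 1]}))


class TestPcoa:
    def test_two_samples_hand_case(self):
        d = pd.DataFrame([[0, 4], [4, 0]], index=["a", "b"], columns=["a", "b"])
        res = community.pcoa(d, n_axes=1)
        assert res.eigenvalues[0] == pytest.approx(8.0)
        np.testing.assert_allclose(sorted(res.coordinates["PCo1"]), [-2, 2], atol=1e-9)

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        res = community.pcoa(d, n_axes=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_zero_distances_give_zero_coordinates(self):
        res = community.pcoa(pd.DataFrame(np.zeros((3, 3))), n_axes=2)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)

    def test_euclidean_distances_recovered_from_coordinates(self):
        rng = np.random.default_rng(1)
        d = random_distance(rng, 8)
        res = community.pcoa(d, n_axes=8)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, d.to_numpy(), atol=1e-9)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        d = random_distance(rng, 10)
        ours = community.pcoa(d, n_axes=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.to_numpy()))
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.iloc[:, :3].to_numpy()),
            atol=1e-8,
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            community.pcoa(pd.DataFrame([[0, 1], [2, 0]]))


TOY_D = np.array(
    [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 1], [10, 10, 1, 0]], dtype=float
)
TOY_LABELS = np.array(["a", "a", "b", "b"])


class TestPermutationTests:
    def test_anosim_r_is_one_on_separated_toy(self):
        res = community.permutation_group_test(TOY_D, TOY_LABELS, method="anosim",
                                               n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-9)

    def test_adonis_p_reaches_add_one_minimum(self):
        rng = np.random.default_rng(0)
        centers = np.repeat([[0.0], [50.0]], 10, axis=0)
        d = squareform(pdist(centers + rng.normal(size=(20, 1))))
        res = community.permutation_group_test(
            d, ["a"] * 10 + ["b"] * 10, method="adonis", n_permutations=199, seed=1
        )
        assert res.p_value == pytest.approx(1 / 200)

    def test_mrpp_delta_smaller_than_permuted_for_structured_data(self):
        res = community.permutation_group_test(TOY_D, TOY_LABELS, method="mrpp",
                                               n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)  # mean within distance
        assert res.p_value < 0.5

    def test_statistics_match_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim, permanova

        rng = np.random.default_rng(5)
        d = random_distance(rng, 12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        dm = skbio.DistanceMatrix(d.to_numpy())
        ours_r = community.permutation_group_test(d, labels, "anosim", 9, 0).statistic
        ours_f = community.permutation_group_test(d, labels, "adonis", 9, 0).statistic
        assert ours_r == pytest.approx(anosim(dm, labels, permutations=9)["test statistic"])
        assert ours_f == pytest.approx(permanova(dm, labels, permutations=9)["test statistic"])

    def test_singleton_group_rejected_for_mrpp_and_adonis(self):
        labels = np.array(["a", "b", "b", "b"])
        for method in ("mrpp", "adonis"):
            with pytest.raises(ValueError):
                community.permutation_group_test(TOY_D, labels, method=method)

    def test_fixed_seed_reproduces_p(self):
        rng = np.random.default_rng(9)
        d = random_distance(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        p1 = community.permutation_group_test(d, labels, "anosim", 199, seed=4).p_value
        p2 = community.permutation_group_test(d, labels, "anosim", 199, seed=4).p_value
        assert p1 == p2


class TestPhenotypePermanova:
    def test_structure_defining_label_reaches_minimum_p(self):
        # 6+6 samples: tight within-group, far between-group distances
        n = 12
        d = np.full((n, n), 10.0)
        d[:6, :6] = 1.0
        d[6:, 6:] = 1.0
        np.fill_diagonal(d, 0.0)
        meta = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        res = community.phenotype_permanova(d, meta, "g", n_permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_constant_variable_rejected(self):
        meta = pd.DataFrame({"g": ["x"] * 4})
        with pytest.raises(ValueError, match="constant"):
            community.phenotype_permanova(TOY_D, meta, "g")

    def test_joint_reordering_leaves_statistic_unchanged(self):
        rng = np.random.default_rng(11)
        d = random_distance(rng, 10)
        meta = pd.DataFrame({"x": rng.normal(size=10)})
        base = community.phenotype_permanova(d, meta, "x", 49, 0).statistic
        perm = rng.permutation(10)
        d2 = pd.DataFrame(d.to_numpy()[np.ix_(perm, perm)])
        meta2 = pd.DataFrame({"x": meta["x"].to_numpy()[perm]})
        assert community.phenotype_permanova(d2, meta2, "x", 49, 0).statistic == pytest.approx(base)

    def test_continuous_variable_matches_skbio_on_categorical_encoding(self):
        # categorical phenotype through the hat-matrix path equals classic
        # PERMANOVA from the independent library
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova

        rng = np.random.default_rng(13)
        d = random_distance(rng, 12)
        labels = np.array(["u"] * 6 + ["v"] * 6)
        meta = pd.DataFrame({"g": labels})
        ours = community.phenotype_permanova(d, meta, "g", 9, 0).statistic
        theirs = permanova(skbio.DistanceMatrix(d.to_numpy()), labels, permutations=9)
        assert ours == pytest.approx(theirs["test statistic"])
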