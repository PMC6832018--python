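"""Marker classifier: candidates, mRMR, LOO-LDA, MCC, SVM, ROC/DeLong."""

import numpy as np
import pandas as pd
import pytest

from oralmgx import classifier, synthetic
from oralmgx.classifier import loo_evaluate, mcc_from_confusion


def independent_lda_loo(X, y, positive):
    """Oracle: separate LDA implementation (explicit Gaussian discriminants
    solved with np.linalg.solve) refit inside a manual LOO loop."""
    n, p = X.shape
    preds = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xt, yt = X[keep], y[keep]
        classes = np.unique(yt)
        mus = [Xt[yt == c].mean(axis=0) for c in classes]
        pooled = sum(
            (Xt[yt == c] - mu).T @ (Xt[yt == c] - mu) for c, mu in zip(classes, mus)
        ) / (len(yt) - 2)
        pooled = pooled + 1e-6 * (np.trace(pooled) / p) * np.eye(p)
        scores = []
        for c, mu in zip(classes, mus):
            w = np.linalg.solve(pooled, mu)
            scores.append(X[i] @ w - 0.5 * mu @ w + np.log((yt == c).mean()))
        preds.append(classes[int(np.argmax(scores))])
    return np.array(preds)


class TestCandidates:
    def test_planted_species_all_selected(self):
        spec = synthetic.CommunitySpec(
            n_species=200, n_samples_per_group=(25, 19),
            differential_species=[
                (f"sp{i:03d}", 2.5, synthetic.CARIES if i % 2 == 0 else synthetic.HEALTHY)
                for i in range(7)
            ],
            seed=1,
        )
        data, truth = synthetic.generate_abundance_matrix(spec, level="species", seed=1)
        candidates = classifier.candidate_features(data.relative, data.labels)
        assert truth.true_informative_markers <= set(candidates)

    def test_p_max_one_selects_everything_variable(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.lognormal(size=(10, 12)),
                              columns=[f"s{i}" for i in range(12)])
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=matrix.columns)
        assert len(classifier.candidate_features(matrix, labels, p_max=1.01)) == 10

    def test_no_candidates_is_an_error(self):
        matrix = pd.DataFrame(np.ones((3, 12)), columns=[f"s{i}" for i in range(12)])
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=matrix.columns)
        with pytest.raises(ValueError, match="relax"):
            classifier.candidate_features(matrix, labels)


class TestMrmr:
    def test_label_identical_feature_ranked_first(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(44)]
        labels = pd.Series(["a"] * 22 + ["b"] * 22, index=cols)
        matrix = pd.DataFrame(
            {
                "noise1": rng.normal(size=44),
                "perfect": (labels == "a").astype(float) + rng.normal(0, 1e-6, 44),
                "noise2": rng.normal(size=44),
            }
        ).T
        matrix.columns = cols
        assert classifier.mrmr_rank(matrix, labels)[0] == "perfect"

    def test_duplicate_feature_maximally_penalised(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(20)]
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=cols)
        signal = (labels == "a").astype(float) + rng.normal(0, 0.2, 20)
        mid = (labels == "a").astype(float) + rng.normal(0, 0.8, 20)
        matrix = pd.DataFrame({"sig": signal, "dup": signal, "mid": mid}).T
        matrix.columns = cols
        order = classifier.mrmr_rank(matrix, labels)
        # one copy is selected first (lexicographic tie-break); its exact
        # duplicate is maximally penalised and falls behind the weaker but
        # non-redundant feature
        assert {order[0], order[-1]} == {"sig", "dup"} and order[1] == "mid"

    def test_single_candidate_trivial_order(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["only"],
                              columns=list("abcd"))
        assert classifier.mrmr_rank(matrix, ["a", "a", "b", "b"]) == ["only"]


class TestMcc:
    def test_hand_values(self):
        assert mcc_from_confusion(2, 2, 0, 0) == pytest.approx(1.0)
        assert mcc_from_confusion(1, 1, 1, 1) == pytest.approx(0.0)
        assert mcc_from_confusion(0, 0, 2, 2) == pytest.approx(-1.0)

    def test_degenerate_denominator_is_zero(self):
        assert mcc_from_confusion(3, 0, 0, 0) == 0.0


class TestLooEvaluate:
    def test_separable_clusters_give_zero_error(self):
        rng = np.random.default_rng(3)
        X = np.r_[rng.normal(0, 0.1, (20, 1)), rng.normal(10, 0.1, (20, 1))]
        y = np.array(["h"] * 20 + ["c"] * 20)
        res = loo_evaluate(X, y, positive="c")
        assert res["error_rate"] == 0.0 and res["mcc"] == pytest.approx(1.0)

    def test_permuted_labels_give_near_zero_mcc(self):
        rng = np.random.default_rng(4)
        mccs = []
        for _ in range(20):
            X = rng.normal(size=(30, 3))
            y = rng.permutation(np.array(["h"] * 15 + ["c"] * 15))
            mccs.append(loo_evaluate(X, y, positive="c")["mcc"])
        assert abs(np.mean(mccs)) < 0.15

    def test_matches_independent_refit_oracle_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(12, 31))
            X = rng.normal(size=(n, 4))
            X[: n // 2] += 1.0
            y = np.array(["c"] * (n // 2) + ["h"] * (n - n // 2))
            ours = loo_evaluate(X, y, positive="c")
            oracle_preds = independent_lda_loo(X, y, "c")
            tp = int(((y == "c") & (oracle_preds == "c")).sum())
            tn = int(((y != "c") & (oracle_preds != "c")).sum())
            fp = int(((y != "c") & (oracle_preds == "c")).sum())
            fn = int(((y == "c") & (oracle_preds != "c")).sum())
            assert ours["error_rate"] == pytest.approx((fp + fn) / n, abs=1e-12)
            assert ours["mcc"] == pytest.approx(mcc_from_confusion(tp, tn, fp, fn), abs=1e-12)


class TestEvaluateSubsets:
    def _separable(self, n_features=12):
        rng = np.random.default_rng(6)
        cols = [f"s{i}" for i in range(40)]
        labels = pd.Series(["c"] * 20 + ["h"] * 20, index=cols)
        rows = {}
        for i in range(n_features):
            shift = 3.0 if i < 6 else 0.0
            rows[f"f{i:02d}"] = np.r_[
                rng.normal(shift, 1, 20), rng.normal(0, 1, 20)
            ]
        return pd.DataFrame(rows, index=cols).T, labels

    def test_panel_is_prefix_of_order(self):
        matrix, labels = self._separable()
        order = list(matrix.index)
        panel = classifier.evaluate_subsets(order, matrix, labels, "c")
        assert panel.panel == order[: len(panel.panel)]
        panel.validate()

    def test_grid_includes_full_set(self):
        matrix, labels = self._separable(n_features=12)
        panel = classifier.evaluate_subsets(list(matrix.index), matrix, labels, "c")
        assert panel.subset_sizes[-1] == 12 and 5 in panel.subset_sizes

    def test_empty_order_rejected(self):
        with pytest.raises(ValueError):
            classifier.evaluate_subsets([], pd.DataFrame(), ["a"], "a")


class TestSvmAndRoc:
    def test_training_error_zero_on_separable_toy(self):
        rng = np.random.default_rng(7)
        cols = [f"s{i}" for i in range(40)]
        matrix = pd.DataFrame(
            {"f1": np.r_[rng.normal(0, 0.2, 20), rng.normal(5, 0.2, 20)],
             "f2": rng.normal(size=40)},
        ).T
        matrix.columns = cols
        labels = pd.Series(["h"] * 20 + ["c"] * 20, index=cols)
        model, proba = classifier.train_and_score(["f1", "f2"], matrix, labels, "c")
        preds = np.where(proba > 0.5, "c", "h")
        assert (preds == labels.to_numpy()).all()

    def test_constant_feature_leaves_score_ranking_unchanged(self):
        rng = np.random.default_rng(8)
        cols = [f"s{i}" for i in range(30)]
        matrix = pd.DataFrame({"f1": rng.normal(size=30)}).T
        matrix.columns = cols
        labels = pd.Series(["h"] * 15 + ["c"] * 15, index=cols)
        m1, _ = classifier.train_and_score(["f1"], matrix, labels, "c")
        with_const = pd.concat(
            [matrix, pd.DataFrame({c: [1.0] for c in cols}, index=["const"])]
        )
        m2, _ = classifier.train_and_score(["f1", "const"], with_const, labels, "c")
        d1 = m1.decision_values(matrix)
        d2 = m2.decision_values(with_const)
        assert (np.argsort(d1) == np.argsort(d2)).all()

    def test_single_class_training_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["a", "b"])
        with pytest.raises(ValueError):
            classifier.train_and_score(["f"], matrix, ["c", "c"], "c")

    def test_auc_hand_enumeration(self):
        scores = [0.9, 0.8, 0.85, 0.1]
        labels = ["p", "p", "n", "n"]
        res = classifier.roc_auc(scores, labels, positive="p")
        assert res.auc == pytest.approx(0.75, abs=1e-9)

    def test_perfect_separation_and_inversion_symmetry(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["p", "p", "n", "n"])
        assert classifier.roc_auc(scores, labels, "p").auc == pytest.approx(1.0)
        assert classifier.roc_auc(scores, labels, "n").auc == pytest.approx(0.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        labels = np.array(["p"] * 15 + ["n"] * 15)
        a1 = classifier.roc_auc(scores, labels, "p").auc
        a2 = classifier.roc_auc(np.exp(3 * scores), labels, "p").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_delong_ci_brackets_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(10)
        widths = []
        for n in (20, 200):
            scores = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
            labels = np.array(["p"] * n + ["n"] * n)
            res = classifier.roc_auc(scores, labels, "p")
            assert res.ci_lower <= res.auc <= res.ci_upper
            widths.append(res.ci_upper - res.ci_lower)
        assert widths[1] < widths[0]

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            classifier.roc_auc([0.1, 0.2], ["p", "p"], "p")


def test_held_out_onset_samples_score_toward_caries():
    """Samples generated near the caries centroid (the caries-onset
    subgroup analogue) receive caries probability > 0.5 in the majority."""
    spec = synthetic.CommunitySpec(
        n_species=50, n_samples_per_group=(30, 20),
        differential_species=[
            (f"sp{i:03d}", 2.5, synthetic.CARIES if i % 2 == 0 else synthetic.HEALTHY)
            for i in range(5)
        ],
        seed=12,
    )
    data, _ = synthetic.generate_abundance_matrix(spec, level="species", seed=12)
    train_cols = [c for c in data.relative.columns if c not in
                  [f"C{i:02d}" for i in range(20, 30)]]
    onset_cols = [f"C{i:02d}" for i in range(20, 30)]
    panel, model, roc = classifier.build_classifier(
        data.relative[train_cols], data.labels[train_cols], positive=synthetic.CARIES
    )
    onset = data.relative[onset_cols]
    # held-out 'onset' cohort: extra caries-like samples from the same community
    feats = np.log10(onset + classifier.LOG_PSEUDOCOUNT)
    proba = model.predict_proba(feats)
    assert (proba > 0.5).mean() > 0.5
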