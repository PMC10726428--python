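"""k-NN and stepwise PCA-LDA classifiers against naive refit oracles."""

import numpy as np
import pandas as pd
import pytest

from ballatac import classify as cl
from ballatac.io_formats import ValidationError


def _frame(X, prefix="f"):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])


class TestKnn:
    def test_training_point_query_k1(self):
        X = _frame([[0, 0], [5, 5], [9, 1]])
        model = cl.knn_fit(X, ["a", "b", "c"], k=1)
        assert cl.knn_predict(model, X.iloc[[1]]) == ["b"]

    def test_single_class_always_wins(self):
        X = _frame(np.random.default_rng(0).normal(size=(6, 3)))
        model = cl.knn_fit(X, ["only"] * 6, k=3)
        assert cl.knn_predict(model, _frame(np.zeros((4, 3)))) == ["only"] * 4

    def test_matches_exhaustive_distance_sort_oracle(self):
        rng = np.random.default_rng(1)
        X = _frame(rng.normal(size=(12, 2)))
        labels = list("aabbccaabbcc")
        model = cl.knn_fit(X, labels, k=3)
        Q = _frame(rng.normal(size=(8, 2)))
        got = cl.knn_predict(model, Q)
        for qi, pred in enumerate(got):
            d = np.linalg.norm(X.to_numpy() - Q.to_numpy()[qi], axis=1)
            order = np.argsort(d, kind="stable")[:3]
            votes = {}
            for idx in order:
                votes[labels[idx]] = votes.get(labels[idx], 0) + 1
            top = max(votes.values())
            winners = [lb for lb, v in votes.items() if v == top]
            want = winners[0] if len(winners) == 1 else labels[order[0]]
            assert pred == want

    def test_tie_broken_by_nearest_neighbor(self):
        # k=2 with one vote each: nearest point's label must win
        X = _frame([[0.0], [1.0], [10.0]])
        model = cl.knn_fit(X, ["near", "far", "far"], k=2)
        assert cl.knn_predict(model, _frame([[0.1]])) == ["near"]

    def test_feature_mismatch_rejected(self):
        model = cl.knn_fit(_frame([[0, 0]]), ["a"], k=1)
        with pytest.raises(ValidationError):
            cl.knn_predict(model, _frame([[0, 0]], prefix="other"))


class TestKnnLoocv:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(2)
        X = np.r_[rng.normal(0, 0.3, size=(8, 4)), rng.normal(10, 0.3, size=(8, 4))]
        conf = cl.knn_loocv(_frame(X), ["lo"] * 8 + ["hi"] * 8, k=3)
        assert conf.accuracy == 1.0

    def test_equals_naive_refit_oracle(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(8, 3)))
        labels = list("aabbabba")
        conf = cl.knn_loocv(X, labels, k=3)
        preds = []
        for i in range(8):
            tr = [j for j in range(8) if j != i]
            m = cl.knn_fit(X.iloc[tr], [labels[j] for j in tr], k=3)
            preds.append(cl.knn_predict(m, X.iloc[[i]])[0])
        oracle = cl.ConfusionMatrix.from_labels(labels, preds)
        assert np.array_equal(conf.matrix, oracle.matrix)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(4)
        C, n = 3, 30
        X = _frame(rng.normal(size=(n, 10)))
        labels = [f"c{i % C}" for i in range(n)]
        conf = cl.knn_loocv(X, labels, k=5)
        sigma = np.sqrt((1 / C) * (1 - 1 / C) / n)
        assert abs(conf.accuracy - 1 / C) <= 3 * sigma + 1e-9


class TestPcaLda:
    @staticmethod
    def _cohort(rng, n_classes=3, n_per=8, n_feat=60, delta=3.0):
        X = rng.normal(size=(n_classes * n_per, n_feat))
        labels = []
        for c in range(n_classes):
            X[c * n_per: (c + 1) * n_per, c * 5: c * 5 + 5] += delta
            labels += [f"c{c}"] * n_per
        return _frame(X), labels

    def test_separable_classes_high_loocv(self):
        X, labels = self._cohort(np.random.default_rng(5))
        model = cl.pca_lda_fit(X, labels, n_pc_grid=range(2, 10))
        assert model.cv_accuracy_ >= 0.9
        pred, _ = cl.pca_lda_predict(model, X)
        assert pred == labels

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(size=(24, 30)))
        labels = ["a"] * 12 + ["b"] * 12
        model = cl.pca_lda_fit(X, labels, n_pc_grid=range(2, 8))
        sigma = np.sqrt(0.25 / 24)
        assert abs(model.cv_accuracy_ - 0.5) <= 3.5 * sigma

    def test_loocv_equals_naive_refit_oracle(self):
        rng = np.random.default_rng(7)
        X, labels = self._cohort(rng, n_classes=3, n_per=5, n_feat=20, delta=1.0)
        grid = [2, 3, 4]
        model = cl.pca_lda_fit(X, labels, n_pc_grid=grid, gamma=0.1)
        y = np.asarray(labels)
        for g in grid:
            preds = []
            for i in range(len(labels)):
                mask = np.ones(len(labels), dtype=bool)
                mask[i] = False
                Xs, c, s = cl._standardize(X.to_numpy()[mask])
                V = cl._pca(Xs, g)
                fold_labels = sorted(set(y[mask]))
                means, Sreg, _ = cl._lda_fit(Xs @ V.T, y[mask], fold_labels, 0.1)
                Zq = (((X.to_numpy()[i] - c) / s)[None, :]) @ V.T
                preds.append(cl._lda_predict(Zq, means, Sreg, fold_labels)[0])
            assert model.grid_accuracies_[g] == pytest.approx(np.mean(np.asarray(preds) == y))

    def test_projection_reproduces_training_scores_bitwise(self):
        rng = np.random.default_rng(8)
        X, labels = self._cohort(rng)
        model = cl.pca_lda_fit(X, labels, n_pc_grid=[3, 4])
        again = model.transform(X)
        assert np.array_equal(again, model.training_scores_)

    def test_midpoint_tie_goes_to_first_label(self):
        means = np.array([[0.0, 0.0], [2.0, 0.0]])
        Sreg = np.eye(2)
        got = cl._lda_predict(np.array([[1.0, 0.0]]), means, Sreg, ["alpha", "beta"])
        assert got == ["alpha"]

    def test_missing_features_reported(self):
        rng = np.random.default_rng(9)
        X, labels = self._cohort(rng)
        model = cl.pca_lda_fit(X, labels, n_pc_grid=[2, 3])
        with pytest.raises(ValidationError, match="features"):
            cl.pca_lda_predict(model, X.iloc[:, :10])

    def test_ties_select_smallest_n_pc(self):
        rng = np.random.default_rng(10)
        X, labels = self._cohort(rng, delta=5.0)  # saturated accuracy over the grid
        model = cl.pca_lda_fit(X, labels, n_pc_grid=[3, 4, 5, 6])
        top = max(model.grid_accuracies_.values())
        assert model.n_pc == min(g for g, a in model.grid_accuracies_.items() if a == top)


class TestCellOfOrigin:
    def test_leukemia_like_samples_assigned_terminal_stage(self):
        """k-NN on progenitor identity loci sends leukemia samples to Pro-B."""
        from ballatac import differential as diff
        from ballatac import synthetic_data as sd

        cm, truth = sd.simulate_progenitors(n_regions=600, n_per_stage=10, n_ball=8, seed=12)
        windows = sd._region_catalog(600, width=250, spacing=1000)
        is_prog = (cm.samples["stage"] != "B-ALL").to_numpy()
        prog = cm.subset_samples(list(cm.samples.index[is_prog]))
        loci = diff.progenitor_identity_loci(prog, windows=windows)
        sf = diff.size_factors(cm)
        z = diff.stabilize(cm, sf, zscore=True).loc[list(loci.ids)].T
        model = cl.knn_fit(z[is_prog], prog.samples["stage"], k=5)
        # progenitor LOOCV separates the staircase cleanly
        conf = cl.knn_loocv(z[is_prog], prog.samples["stage"], k=5)
        assert conf.accuracy >= 0.9
        preds = cl.knn_predict(model, z[~is_prog])
        assert np.mean(np.asarray(preds) == "ProB") > 0.5


class TestMergeClassesAccuracy:
    def _conf(self):
        return cl.ConfusionMatrix(["a", "b", "c"], [[5, 2, 0], [1, 6, 1], [0, 0, 7]])

    def test_identity_partition_unchanged(self):
        conf = self._conf()
        assert cl.merge_classes_accuracy(conf, [["a"], ["b"], ["c"]]) == conf.accuracy

    def test_single_group_gives_one(self):
        assert cl.merge_classes_accuracy(self._conf(), [["a", "b", "c"]]) == 1.0

    def test_hand_collapsed_pair(self):
        # merging a and b: correct = (5+2+1+6) + 7 = 21 of 22
        assert cl.merge_classes_accuracy(self._conf(), [["a", "b"], ["c"]]) == pytest.approx(21 / 22)

    def test_coarsening_monotone(self):
        conf = self._conf()
        fine = cl.merge_classes_accuracy(conf, [["a"], ["b"], ["c"]])
        mid = cl.merge_classes_accuracy(conf, [["a", "b"], ["c"]])
        coarse = cl.merge_classes_accuracy(conf, [["a", "b", "c"]])
        assert fine <= mid <= coarse

    def test_non_partition_rejected(self):
        with pytest.raises(ValidationError):
            cl.merge_classes_accuracy(self._conf(), [["a", "b"], ["b", "c"]])
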