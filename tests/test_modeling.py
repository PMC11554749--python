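import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import mutual_info_score

from afmi import modeling as md


def brute_force_mrmr(X: pd.DataFrame, y, n_select: int):
    """Independent MIQ greedy ranking: quantile binning + sklearn MI,
    recomputing relevance/redundancy from scratch at every step."""

    def bin10(x):
        edges = np.unique(np.quantile(x, np.linspace(0, 1, 11)[1:-1]))
        return np.searchsorted(edges, x, side="left")

    names = list(X.columns)
    binned = {c: bin10(X[c].to_numpy()) for c in names}
    yv = np.asarray(y)
    relevance = {c: mutual_info_score(binned[c], yv) for c in names}
    selected = []
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for c in sorted(set(names) - set(selected)):
            if not selected:
                score = relevance[c]
            else:
                w = np.mean(
                    [mutual_info_score(binned[c], binned[s]) for s in selected]
                )
                score = relevance[c] / (w + 1e-12)
            if score > best_score:
                best, best_score = c, score
        selected.append(best)
    return selected


class TestMRMR:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            {
                "noise_a": rng.normal(size=n),
                "label_copy": y.astype(float),
                "noise_b": rng.normal(size=n),
            }
        )
        names, _ = md.mrmr_rank(X, y, 3)
        assert names[0] == "label_copy"

    def test_redundant_copy_not_ranked_second(self):
        rng = np.random.default_rng(1)
        n = 400
        y = rng.integers(0, 2, n)
        strong = y + 0.1 * rng.normal(size=n)
        weak = y + 1.0 * rng.normal(size=n)
        X = pd.DataFrame(
            {
                "a_strong": strong,
                "b_copy_of_strong": strong,
                "c_weak_informative": weak,
                "d_noise": rng.normal(size=n),
            }
        )
        names, _ = md.mrmr_rank(X, y, 4)
        assert names[0] in ("a_strong", "b_copy_of_strong")
        assert names[1] == "c_weak_informative"

    def test_full_selection_is_a_permutation(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            rng.normal(size=(60, 5)), columns=[f"f{i}" for i in range(5)]
        )
        y = rng.integers(0, 2, 60)
        names, scores = md.mrmr_rank(X, y, 5)
        assert sorted(names) == sorted(X.columns)
        assert len(scores) == 5

    def test_n_select_above_n_features_rejected(self):
        X = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="n_select"):
            md.mrmr_rank(X, np.r_[np.zeros(5), np.ones(5)], 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, p = 80, rng.integers(3, 7)
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            rng.normal(size=(n, p)) + 0.5 * y[:, None] * rng.normal(size=p),
            columns=[f"f{j}" for j in range(p)],
        )
        ours, _ = md.mrmr_rank(X, y, p)
        oracle = brute_force_mrmr(X, y, p)
        assert ours == oracle


class TestZscore:
    def test_train_equals_test_standardised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(3, 2, size=(50, 4)), columns=list("abcd"))
        tr, te, st = md.zscore_fit_apply(df, df)
        np.testing.assert_allclose(te.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(te.std(ddof=1), 1, rtol=1e-12)

    def test_constant_feature_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            tr, _, st = md.zscore_fit_apply(df)
        assert list(tr.columns) == ["a"]
        assert st["dropped"] == ["c"]

    def test_shift_scales_by_train_sd(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(0, 4, 100)})
        _, te1, st = md.zscore_fit_apply(df, df)
        _, te2, _ = md.zscore_fit_apply(df, df + 10)
        np.testing.assert_allclose(
            te2["a"] - te1["a"], 10 / st["sd"]["a"], rtol=1e-12
        )


class TestEmbedding:
    def test_two_class_direction_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n, p = 2000, 6
        A = rng.normal(size=(p, p)) * 0.4
        cov = A @ A.T + np.eye(p)
        delta = rng.normal(size=p)
        delta *= 2.0 / np.linalg.norm(delta)
        y = np.repeat([0, 1], n // 2)
        X = rng.multivariate_normal(np.zeros(p), cov, n) + y[:, None] * delta
        emb = md.DiscriminantEmbedding(n_select=p, pca_var=1.0).fit(
            pd.DataFrame(X), y
        )
        # effective linear map of the fitted embedding
        base = emb.transform(np.zeros((1, p)))
        w = (emb.transform(np.eye(p)) - base).ravel()
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        pooled = ((X[y == 0] - mu0).T @ (X[y == 0] - mu0)
                  + (X[y == 1] - mu1).T @ (X[y == 1] - mu1)) / (n - 2)
        w_star = np.linalg.solve(pooled, mu1 - mu0)
        cos = abs(w @ w_star) / (np.linalg.norm(w) * np.linalg.norm(w_star))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_transform_is_pure(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(100, 10)))
        y = rng.integers(0, 3, 100)
        emb = md.DiscriminantEmbedding(n_select=8).fit(X, y)
        z1, z2 = emb.transform(X), emb.transform(X)
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (100, 2)
        # refitting on the same data reproduces coordinates exactly
        z3 = md.DiscriminantEmbedding(n_select=8).fit(X, y).transform(X)
        np.testing.assert_allclose(z1, z3, atol=1e-10)

    def test_label_permutation_destroys_separation(self):
        rng = np.random.default_rng(2)
        n = 300
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 5)) + 3 * y[:, None])
        true_fit = md.DiscriminantEmbedding(n_select=5).fit(X, y)
        perm_fit = md.DiscriminantEmbedding(n_select=5).fit(
            X, rng.permutation(y)
        )
        assert perm_fit.eigenvalues_[0] < true_fit.eigenvalues_[0]

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"a": rng.normal(size=40), "b": np.ones(40), "c": rng.normal(size=40)}
        )
        y = rng.integers(0, 2, 40)
        with pytest.warns(UserWarning, match="zero-variance"):
            emb = md.DiscriminantEmbedding(n_select=2).fit(X, y)
        assert emb.kept_features_ == ["a", "c"]


class TestADASYN:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        X2, y2 = md.adasyn_upsample(X, y, seed=0)
        assert len(X2) == 40
        np.testing.assert_array_equal(X2, X)

    def test_counts_balance_exactly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(1, 1, (15, 2))])
        y = np.r_[np.zeros(60), np.ones(15)]
        X2, y2 = md.adasyn_upsample(X, y, seed=1)
        _, counts = np.unique(y2, return_counts=True)
        assert abs(counts[0] - counts[1]) <= 5

    def test_synthetic_points_are_segment_interpolations(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(1.5, 1, (10, 2))])
        y = np.r_[np.zeros(50), np.ones(10)]
        X2, y2 = md.adasyn_upsample(X, y, seed=2)
        minority = X[y == 1]
        for pt in X2[len(X):]:
            # must be a convex combination of two minority points
            found = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    d = minority[j] - minority[i]
                    nrm = d @ d
                    lam = (pt - minority[i]) @ d / nrm if nrm > 0 else 0.0
                    cand = minority[i] + lam * d
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(pt, cand, atol=1e-9):
                        found = True
                        break
                if found:
                    break
            assert found

    def test_seeded_and_deterministic(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(2, 1, (8, 2))])
        y = np.r_[np.zeros(30), np.ones(8)]
        a = md.adasyn_upsample(X, y, seed=7)
        b = md.adasyn_upsample(X, y, seed=7)
        np.testing.assert_array_equal(a[0], b[0])

    def test_minority_too_small_rejected(self):
        X = np.zeros((10, 2))
        y = np.r_[np.zeros(7), np.ones(3)]
        with pytest.raises(ValueError, match="minority"):
            md.adasyn_upsample(X, y, k_density=5)


class TestDownsample:
    def test_majority_reduced_to_minority_count(self):
        y = np.r_[np.zeros(100), np.ones(40)]
        idx = md.downsample_majority(y, seed=0)
        _, counts = np.unique(y[idx], return_counts=True)
        assert counts.tolist() == [40, 40]

    def test_balanced_is_identity(self):
        y = np.repeat([0, 1], 30)
        idx = md.downsample_majority(y, seed=0)
        assert len(idx) == 60

    def test_different_seeds_same_counts(self):
        y = np.r_[np.zeros(50), np.ones(20)]
        a = md.downsample_majority(y, seed=1)
        b = md.downsample_majority(y, seed=2)
        assert len(a) == len(b) == 40
        assert not np.array_equal(a, b)


class TestAUC:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_mann_whitney_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(10, 60, 2)
        y = np.r_[np.zeros(n0), np.ones(n1)]
        s = np.r_[rng.normal(0, 1, n0), rng.normal(0.5, 1.3, n1)]
        ours = md.auc_from_scores(y, s, pos_label=1)
        u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert ours == pytest.approx(u / (n1 * n0), abs=1e-10)


class TestCrossvalidate:
    def _toy(self, n=200, sep=5.0, seed=0, p=6):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            rng.normal(size=(n, p)) + sep * y[:, None] * np.r_[1, np.zeros(p - 1)],
            columns=[f"f{j}" for j in range(p)],
        )
        return X, y

    @pytest.mark.parametrize("kind", ["linear_svm", "polynomial_svm", "lda"])
    def test_separable_data_gives_perfect_auc(self, kind):
        X, y = self._toy(sep=8.0)
        rep = md.crossvalidate(
            X, y, classifier=md.ClassifierSpec(kind=kind), seed=0
        )
        assert rep.fold_auc == [1.0] * 5
        assert rep.auc_mean == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        X, y = self._toy(n=300, sep=5.0, seed=1)
        rng = np.random.default_rng(42)
        rep = md.crossvalidate(X, rng.permutation(y), seed=1)
        assert 0.35 <= rep.auc_mean <= 0.65

    def test_small_class_rejected(self):
        X, y = self._toy(n=20)
        y = np.r_[np.zeros(17), np.ones(3)]
        with pytest.raises(ValueError, match="fewer than"):
            md.crossvalidate(X, y, n_folds=5)

    def test_report_fields_within_bounds(self):
        X, y = self._toy(n=120, sep=1.0, seed=3)
        rep = md.crossvalidate(X, y, resample="downsample", seed=3)
        assert len(rep.fold_auc) == 5
        assert all(0 <= a <= 1 for a in rep.fold_auc)
        assert all(0 <= s <= 1 for s in rep.fold_sensitivity)
        assert all(0 <= s <= 1 for s in rep.fold_specificity)
        d = rep.to_dict()
        assert d["n_per_class"] == {"0": 60, "1": 60}

    def test_training_canary_reaches_perfect_auc(self):
        rng = np.random.default_rng(4)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 10)))
        y = rng.integers(0, 2, n)
        X["canary"] = y + 0.01 * rng.normal(size=n)
        rep = md.crossvalidate(X, y, seed=4)
        assert rep.auc_mean == 1.0

    def test_test_only_canary_stays_at_chance(self):
        rng = np.random.default_rng(5)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 10)))
        y = rng.integers(0, 2, n)
        canary = rng.normal(size=n)
        test_idx = np.arange(0, n, 2)
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        canary[test_idx] = y[test_idx]
        X["canary"] = canary
        rep = md.crossvalidate(
            X, y, cv=[(train_idx, test_idx), (test_idx, train_idx)]
        )
        assert 0.35 <= rep.fold_auc[0] <= 0.65


class TestLineHeterogeneity:
    def test_exchangeable_lines_controlled(self):
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(5):
            table = pd.DataFrame(
                rng.normal(size=(150, 47)),
                columns=[f"ch{k:02d}_mean" for k in range(47)],
            )
            lines = np.repeat(["L0", "L1", "L2"], 50)
            fracs.append(md.line_heterogeneity(table, lines).fraction_significant)
        assert max(fracs) <= 0.15

    def test_shifted_line_detected_in_all_shifted_channels(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.normal(size=(150, 47)),
            columns=[f"ch{k:02d}_mean" for k in range(47)],
        )
        lines = np.repeat(["L0", "L1", "L2"], 50)
        shifted = list(range(20))
        table.loc[lines == "L0", [f"ch{k:02d}_mean" for k in shifted]] += 3.0
        rep = md.line_heterogeneity(table, lines)
        assert all(rep.significant[k] for k in shifted)

    def test_single_line_rejected(self):
        table = pd.DataFrame(np.zeros((10, 2)), columns=["ch00_mean", "ch01_mean"])
        with pytest.raises(ValueError, match="lines"):
            md.line_heterogeneity(table, ["L0"] * 10)
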