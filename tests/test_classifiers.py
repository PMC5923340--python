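"""Splits, elastic-net logistic regression (with a scikit-learn
cross-check), LDA, PLS-DA/VIP and the cross-model consensus table."""

import numpy as np
import pandas as pd
import pytest

from omistrat.cohort_io import CohortMetadata, CohortValidationError
from omistrat.classifiers import (
    ElasticNetConfig,
    compare_models,
    enet_logistic_path,
    fit_elastic_net,
    fit_elastic_net_both,
    fit_lda,
    fit_plsda,
    lambda_max,
    make_split,
    weighted_center,
)


def _meta(n_s=9, n_ns=8):
    idx = pd.Index([f"P{i:02d}" for i in range(n_s + n_ns)], name="sample_id")
    return CohortMetadata(
        pd.DataFrame({"group": ["S"] * n_s + ["NS"] * n_ns}, index=idx)
    )


class TestMakeSplit:
    def test_two_thirds_stratified_on_reference_shape(self):
        split = make_split(_meta(9, 8), seed=0)
        groups = _meta(9, 8).groups
        train_s = sum(groups[p] == "S" for p in split.train)
        train_ns = sum(groups[p] == "NS" for p in split.train)
        assert (train_s, train_ns) == (6, 5)
        assert len(split.test) == 6
        assert set(split.train) | set(split.test) == set(groups.index)
        assert set(split.train) & set(split.test) == set()

    def test_deterministic_under_seed(self):
        a = make_split(_meta(), seed=5)
        b = make_split(_meta(), seed=5)
        assert a.train == b.train and a.test == b.test

    def test_different_seeds_differ(self):
        a = make_split(_meta(20, 20), stratified=False, seed=1)
        b = make_split(_meta(20, 20), stratified=False, seed=2)
        assert a.train != b.train

    def test_tiny_class_rejected(self):
        with pytest.raises(CohortValidationError, match="NS"):
            make_split(_meta(5, 1))


def _separable(rng, n=60, p=20, informative=3, shift=2.0):
    y = (np.arange(n) % 2).astype(float)
    X = rng.standard_normal((n, p))
    signs = [1.0, -1.0, 1.0]
    for j in range(informative):
        X[:, j] += signs[j % 3] * shift * (2 * y - 1)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    cols = [f"f{j}" for j in range(p)]
    n_tr = int(n * 2 / 3)
    return (pd.DataFrame(X[:n_tr], columns=cols), y[:n_tr],
            pd.DataFrame(X[n_tr:], columns=cols), y[n_tr:], signs)


class TestElasticNet:
    def test_huge_lambda_leaves_only_prevalence_intercept(self, rng):
        Xtr, ytr, _, _, _ = _separable(rng)
        w = enet_logistic_path(Xtr.to_numpy(), ytr, 0.5,
                               np.array([1e4]))[0]
        assert np.allclose(w[1:], 0.0)
        prev = ytr.mean()
        assert w[0] == pytest.approx(np.log(prev / (1 - prev)), abs=1e-4)

    def test_l1_norm_shrinks_along_increasing_lambda(self, rng):
        Xtr, ytr, _, _, _ = _separable(rng, n=30, p=8, shift=1.0)
        lm = lambda_max(Xtr.to_numpy(), ytr, 0.5)
        lams = np.geomspace(lm, lm * 1e-3, 40)
        path = enet_logistic_path(Xtr.to_numpy(), ytr, 0.5, lams)
        l1 = np.abs(path[:, 1:]).sum(axis=1)
        # lambdas descend along the path, so the l1 norm grows (weakly)
        assert (np.diff(l1) >= -1e-6).all()
        assert np.allclose(path[0, 1:], 0.0, atol=1e-8)

    def test_agrees_with_sklearn_at_fixed_lambda(self, rng):
        from sklearn.linear_model import LogisticRegression

        Xtr, ytr, _, _, _ = _separable(rng, n=40, p=6, shift=0.8)
        X = Xtr.to_numpy()
        n = X.shape[0]
        lam = 0.05
        w = enet_logistic_path(X, ytr, 0.5, np.array([lam]), tol=1e-10,
                               max_iter=20000)[0]
        sk = LogisticRegression(
            l1_ratio=0.5, C=1.0 / (n * lam),
            solver="saga", tol=1e-10, max_iter=200000,
        ).fit(X, ytr)
        np.testing.assert_allclose(w[1:], sk.coef_[0], atol=2e-4)
        assert w[0] == pytest.approx(sk.intercept_[0], abs=2e-4)

    def test_planted_signal_recovered_by_both_strategies(self, rng):
        Xtr, ytr, Xte, yte, signs = _separable(rng, n=60, p=20,
                                               informative=3)
        cfg = ElasticNetConfig(n_repetitions=10, seed=0)
        both = fit_elastic_net_both(Xtr, ytr, Xte, yte, cfg)
        for res in both.values():
            coefs = res.coefficients
            for j in range(3):
                assert coefs[f"f{j}"] != 0.0
                assert np.sign(coefs[f"f{j}"]) == signs[j]
            assert res.all_test_correct

    def test_strategy_b_refit_beats_null_deviance(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=30, p=10)
        res = fit_elastic_net(Xtr, ytr, Xte, yte,
                              ElasticNetConfig(n_repetitions=5, strategy="B",
                                               seed=1))
        w = np.concatenate([[res.intercept], res.coefficients.to_numpy()])
        Xa = np.hstack([np.ones((len(ytr), 1)), Xtr.to_numpy()])
        mu = 1 / (1 + np.exp(-Xa @ w))
        dev = -2 * np.sum(ytr * np.log(mu) + (1 - ytr) * np.log(1 - mu))
        prev = ytr.mean()
        dev_null = -2 * len(ytr) * (prev * np.log(prev)
                                    + (1 - prev) * np.log(1 - prev))
        assert dev <= dev_null + 1e-9

    def test_single_class_training_labels_rejected(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=12, p=4)
        with pytest.raises(CohortValidationError, match="single class"):
            fit_elastic_net(Xtr, np.ones_like(ytr), Xte, yte)


class TestLda:
    def test_one_dimensional_threshold_at_midpoint(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 4.0, 5.0, 6.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        res = fit_lda(X, y, X, y, shrinkage=None)
        w, b = res.coefficients["x"], res.intercept
        # decision value crosses zero at (m0 + m1) / 2 = 3 under equal priors
        assert -b / w == pytest.approx(3.0)

    def test_duplicate_feature_without_shrinkage_is_singular(self, rng):
        X, y = _separable(rng, n=30, p=4)[0:2]
        X = X.copy()
        X["dup"] = X["f0"]
        with pytest.raises(CohortValidationError, match="shrinkage"):
            fit_lda(X, y, X.iloc[:2], y[:2], shrinkage=None)

    def test_label_swap_negates_boundary(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=40, p=5)
        a = fit_lda(Xtr, ytr, Xte, yte)
        b = fit_lda(Xtr, 1 - ytr, Xte, 1 - yte)
        np.testing.assert_allclose(a.coefficients, -b.coefficients,
                                   atol=1e-10)
        assert a.intercept == pytest.approx(-b.intercept, abs=1e-10)

    def test_agrees_with_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        Xtr, ytr, Xte, yte, _ = _separable(rng, n=40, p=5, shift=1.0)
        res = fit_lda(Xtr, ytr, Xte, yte, shrinkage=None, priors="empirical")
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(Xtr, ytr)
        np.testing.assert_array_equal(
            res.predictions["predicted"].to_numpy(), sk.predict(Xte)
        )


class TestPlsda:
    def test_weighted_equals_ordinary_centering_when_balanced(self, rng):
        X = rng.standard_normal((20, 7))
        y = np.arange(20) % 2
        diff = weighted_center(X, y) - X.mean(axis=0)
        assert np.abs(diff).max() < 1e-12

    def test_unbalanced_centering_averages_class_means(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array([0] * 9 + [1] * 3)
        expected = 0.5 * (X[y == 0].mean(0) + X[y == 1].mean(0))
        np.testing.assert_allclose(weighted_center(X, y), expected)

    def test_vip_mean_square_is_one(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=30, p=12)
        res = fit_plsda(Xtr, ytr, Xte, yte, n_components=3)
        assert float((res.vip ** 2).mean()) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_features_share_vip(self, rng):
        n = 20
        y = np.arange(n) % 2
        base = 1.5 * (2 * y - 1) + rng.standard_normal(n)
        X = pd.DataFrame({"a": base, "b": base.copy(),
                          "c": rng.standard_normal(n)})
        res = fit_plsda(X, y, X, y, n_components=2)
        assert res.vip["a"] == pytest.approx(res.vip["b"], abs=1e-10)

    def test_component_bound_enforced(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=6, p=3)
        with pytest.raises(CohortValidationError, match="bound"):
            fit_plsda(Xtr, ytr, Xte, yte, n_components=5)

    def test_scores_match_sklearn_on_balanced_data(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        Xtr, ytr, Xte, yte, _ = _separable(rng, n=24, p=8, shift=1.0)
        res = fit_plsda(Xtr, ytr, Xte, yte, n_components=3)
        sk = PLSRegression(n_components=3, scale=False).fit(
            Xtr, 2.0 * ytr - 1.0
        )
        # balanced classes: weighted centering == sklearn's mean centering,
        # so latent scores agree up to per-component sign
        for a in range(3):
            mine = res.scores.iloc[:, a].to_numpy()
            theirs = sk.x_scores_[:, a]
            assert (np.allclose(mine, theirs, atol=1e-8)
                    or np.allclose(mine, -theirs, atol=1e-8))

    def test_agrees_with_lda_on_separated_data(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=36, p=10, shift=3.0)
        lda = fit_lda(Xtr, ytr, Xte, yte)
        pls = fit_plsda(Xtr, ytr, Xte, yte)
        assert lda.all_test_correct and pls.all_test_correct


class TestCompareModels:
    def test_consensus_membership_and_na(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=40, p=6, shift=2.0)
        lda = fit_lda(Xtr, ytr, Xte, yte, tier="metabolites", top_k=6)
        pls = fit_plsda(Xtr.iloc[:, :4], ytr, Xte.iloc[:, :4], yte,
                        n_components=2, tier="metabolites", top_k=4)
        table = compare_models([lda, pls])
        sel_cols = [c for c in table.columns if c.startswith("selected[")]
        pls_col = [c for c in sel_cols if "plsda" in c][0]
        assert pd.isna(table.loc["f5", pls_col])  # f5 never entered PLS-DA
        assert table.loc["f0", "sign_consistent"] in (True, False)

    def test_feature_selected_everywhere_is_flagged(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=40, p=4, shift=3.0)
        lda = fit_lda(Xtr, ytr, Xte, yte)
        pls = fit_plsda(Xtr, ytr, Xte, yte, n_components=2)
        table = compare_models([lda, pls])
        strong = table.loc["f0"]
        if strong[[c for c in table.columns
                   if c.startswith("selected[")]].eq(True).all():
            assert bool(strong["selected_by_all"])

    def test_requires_two_models(self, rng):
        Xtr, ytr, Xte, yte, _ = _separable(rng, n=20, p=3)
        lda = fit_lda(Xtr, ytr, Xte, yte)
        with pytest.raises(ValueError):
            compare_models([lda])
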