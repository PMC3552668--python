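"""Screening tests and PCA: statistics, routing, decorrelation identities."""

import math

import numpy as np
import pandas as pd
import pytest

from cgimethpred import chi2_test, fisher_test, ks_test, pca_fit, screen, transform
from cgimethpred.feature_extractor import FeatureMatrix
from cgimethpred.feature_selector import (
    SelectionError,
    SelectionModel,
    fit_selection,
    inverse_transform,
)

from oracles import naive_fisher_two_sided, naive_ks_statistic


def _matrix(values: np.ndarray, categories=None, prefix="f"):
    n, p = values.shape
    names = [f"{prefix}{j}" for j in range(p)]
    cats = categories or {name: "histone_methylation" for name in names}
    data = pd.DataFrame(
        values, columns=names,
        index=pd.Index([f"i{k}" for k in range(n)], name="island_id"),
    )
    return FeatureMatrix(data=data, categories=cats)


class TestKsTest:
    def test_identical_samples(self):
        d, p = ks_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_samples(self):
        d, _ = ks_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    def test_hand_derived_statistic(self):
        # brute-force ECDF sup over breakpoints gives 0.5
        pos, neg = [1, 2, 3, 4], [3, 4, 5, 6]
        assert naive_ks_statistic(pos, neg) == 0.5
        d, _ = ks_test(pos, neg)
        assert d == pytest.approx(0.5)

    def test_matches_naive_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(size=rng.integers(5, 30))
            d, _ = ks_test(a, b)
            assert d == pytest.approx(naive_ks_statistic(list(a), list(b)))

    def test_too_small_group_rejected(self):
        with pytest.raises(SelectionError):
            ks_test([1.0], [1.0, 2.0])


class TestChi2Test:
    def test_balanced_table_statistic_zero(self):
        # 10 of value 0 and 10 of value 1 in each class
        feature = [0] * 10 + [1] * 10 + [0] * 10 + [1] * 10
        labels = [0] * 20 + [1] * 20
        stat, p = chi2_test(feature, labels)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # 2x2 table [[20,0],[0,20]]: Pearson chi2 = n = 40
        feature = [0] * 20 + [1] * 20
        labels = [0] * 20 + [1] * 20
        stat, p = chi2_test(feature, labels)
        assert stat == pytest.approx(40.0)
        assert p < 1e-9

    def test_constant_feature_not_selectable(self):
        stat, p = chi2_test([2] * 30, [0] * 15 + [1] * 15)
        assert (stat, p) == (0.0, 1.0)

    def test_rare_values_pooled(self):
        # values 5..9 appear once each; pooled they form one "other" row
        feature = [0] * 20 + [1] * 20 + [5, 6, 7, 8, 9]
        labels = [0] * 20 + [1] * 20 + [1] * 5
        stat, p = chi2_test(feature, labels)
        assert math.isfinite(stat) and 0 <= p <= 1


class TestFisherTest:
    def test_balanced_table(self):
        feature = [0] * 5 + [1] * 5 + [0] * 5 + [1] * 5
        labels = [0] * 10 + [1] * 10
        assert fisher_test(feature, labels) == pytest.approx(1.0)

    def test_perfect_separation_enumeration(self):
        # [[10,0],[0,10]]: p = 2 / C(20,10)
        feature = [0] * 10 + [1] * 10
        labels = [0] * 10 + [1] * 10
        expected = 2 / math.comb(20, 10)
        assert fisher_test(feature, labels) == pytest.approx(expected)
        assert naive_fisher_two_sided([[10, 0], [0, 10]]) == pytest.approx(
            expected
        )

    def test_all_zero_feature(self):
        assert fisher_test([0] * 20, [0] * 10 + [1] * 10) == 1.0

    def test_matches_naive_enumeration(self, rng):
        for _ in range(10):
            feature = rng.integers(0, 2, size=24)
            labels = rng.integers(0, 2, size=24)
            if len(np.unique(labels)) < 2 or len(np.unique(feature)) < 2:
                continue
            a = int(np.sum((feature == 0) & (labels == 0)))
            b = int(np.sum((feature == 0) & (labels == 1)))
            c = int(np.sum((feature != 0) & (labels == 0)))
            d = int(np.sum((feature != 0) & (labels == 1)))
            assert fisher_test(feature, labels) == pytest.approx(
                naive_fisher_two_sided([[a, b], [c, d]]), rel=1e-9
            )


class TestScreen:
    def test_constant_feature_never_retained(self):
        X = np.ones((40, 1))
        labels = [0] * 20 + [1] * 20
        model = screen(_matrix(X), labels)
        assert model.retained_features == []
        assert model.p_values["f0"] == 1.0

    def test_planted_signal_recovery(self, rng):
        """All 10 planted features (5-sd class separation) are retained;
        about 5% of the 100 noise features come along (binomial range)."""
        n = 200
        labels = np.array([0] * 100 + [1] * 100)
        noise = rng.normal(size=(n, 100))
        planted = rng.normal(size=(n, 10)) + 5.0 * labels[:, None]
        X = np.hstack([planted, noise])
        model = screen(_matrix(X), labels)
        planted_names = {f"f{j}" for j in range(10)}
        retained = set(model.retained_features)
        assert planted_names <= retained
        n_noise = len(retained - planted_names)
        # Binomial(100, 0.05): 99% interval roughly [0, 12]
        assert n_noise <= 12

    def test_row_permutation_invariant(self, rng):
        X = rng.normal(size=(60, 8))
        labels = rng.integers(0, 2, size=60)
        while len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 2, size=60)
        perm = rng.permutation(60)
        a = screen(_matrix(X), labels)
        b = screen(_matrix(X[perm]), labels[perm])
        assert a.p_values == pytest.approx(b.p_values)

    def test_test_routing_by_category(self, rng):
        cats = {
            "gene_function_oncogene": "gene_function",
            "tfbs_G1_count": "tfbs",
            "tfbs_G1_avgscore": "tfbs",
            "length": "general",
        }
        X = np.column_stack([
            rng.integers(0, 2, size=40),
            rng.integers(0, 4, size=40),
            rng.normal(size=40),
            rng.normal(size=40),
        ]).astype(float)
        data = pd.DataFrame(X, columns=list(cats),
                            index=pd.Index([f"i{k}" for k in range(40)],
                                           name="island_id"))
        m = FeatureMatrix(data=data, categories=cats)
        labels = [0] * 20 + [1] * 20
        model = screen(m, labels)
        assert model.test_used["gene_function_oncogene"] == "fisher"
        assert model.test_used["tfbs_G1_count"] == "chi2"
        assert model.test_used["tfbs_G1_avgscore"] == "ks"
        assert model.test_used["length"] == "ks"

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(SelectionError):
            screen(_matrix(X), [1] * 10)


class TestPca:
    def _screened(self, X, labels=None):
        m = _matrix(X)
        model = SelectionModel()
        model.retained_features = list(m.data.columns)
        return m, model

    def test_perfectly_correlated_features_one_component(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x + 3])
        m, model = self._screened(X)
        pca_fit(model, m, variance_threshold=0.5)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert model.k == 1

    def test_cumulative_rule(self):
        from cgimethpred.feature_selector import components_for_threshold

        # ratios (0.6, 0.3, 0.08, 0.02) at threshold 0.90 -> k = 2
        ratios = np.array([0.6, 0.3, 0.08, 0.02])
        assert components_for_threshold(ratios, 0.90) == 2
        assert components_for_threshold(ratios, 0.95) == 3
        assert components_for_threshold(ratios, 1.0) == 4

    def test_full_rank_properties(self, rng):
        X = rng.normal(size=(60, 6))
        m, model = self._screened(X)
        pca_fit(model, m, variance_threshold=0.999)
        assert np.sum(model.explained_variance_ratio) == pytest.approx(1.0)
        C = model.pca_components
        np.testing.assert_allclose(C @ C.T, np.eye(len(C)), atol=1e-8)
        # non-increasing ratios
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_transform_decorrelates_training_data(self, rng):
        X = rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5))
        m, model = self._screened(X)
        pca_fit(model, m, variance_threshold=1.0)
        scores = transform(model, m)
        corr = np.corrcoef(scores, rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 1e-8
        # column variances equal the eigenvalues
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.explained_variance[: model.k],
            rtol=1e-8,
        )

    def test_inverse_transform_recovers_standardized_data(self, rng):
        X = rng.normal(size=(40, 4))
        m, model = self._screened(X)
        pca_fit(model, m, variance_threshold=1.0)
        scores = transform(model, m)
        Z = inverse_transform(model, scores)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        np.testing.assert_allclose(Z, (X - mu) / sd, atol=1e-8)

    def test_k_monotone_in_threshold(self, rng):
        X = rng.normal(size=(50, 10)) @ rng.normal(size=(10, 10))
        labels = rng.integers(0, 2, size=50)
        ks = []
        for thr in (0.999, 0.99, 0.9, 0.5):
            m, model = self._screened(X)
            pca_fit(model, m, variance_threshold=thr)
            ks.append(model.k)
        assert ks == sorted(ks, reverse=True)

    def test_duplicate_row_maps_identically(self, rng):
        X = rng.normal(size=(30, 4))
        m, model = self._screened(X)
        pca_fit(model, m)
        dup = m.subset_rows([m.island_ids[0]])
        a = transform(model, dup)
        b = transform(model, m)[0:1]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_missing_column_named_in_error(self, rng):
        X = rng.normal(size=(30, 3))
        m, model = self._screened(X)
        pca_fit(model, m)
        reduced = FeatureMatrix(
            data=m.data[["f0", "f1"]].copy(),
            categories={c: m.categories[c] for c in ["f0", "f1"]},
        )
        with pytest.raises(SelectionError, match="f2"):
            transform(model, reduced)

    def test_empty_retained_set_explicit_error(self, rng):
        X = rng.normal(size=(30, 3))
        m = _matrix(X)
        model = SelectionModel()  # nothing retained
        with pytest.raises(SelectionError, match="retained no features"):
            pca_fit(model, m)

    def test_json_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(30, 4))
        labels = np.array([0] * 15 + [1] * 15)
        X[:, 0] += 3 * labels
        model = fit_selection(_matrix(X), labels, alpha=0.5)
        path = tmp_path / "sel.json"
        model.to_json(path)
        again = SelectionModel.from_json(path)
        assert again.retained_features == model.retained_features
        assert again.k == model.k
        np.testing.assert_allclose(again.pca_components, model.pca_components)
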