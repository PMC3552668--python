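"""Univariate statistical screening followed by PCA decorrelation.

Screening routes each feature to a test by its category: Fisher's exact
test for the binary gene-function indicators, Pearson chi-squared for the
count-valued TFBS / conserved-element features, and the two-sample
Kolmogorov-Smirnov test for every other numeric feature.  A feature is
retained when its p-value is below alpha (0.05 by default, no multiplicity
correction).  Retained features are standardized to zero mean and unit sd
and decorrelated by PCA; the number of retained components k is the
smallest prefix whose cumulative explained-variance ratio reaches the
variance threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .feature_extractor import FeatureMatrix

logger = logging.getLogger("cgimethpred")

DEFAULT_ALPHA = 0.05
DEFAULT_VARIANCE_THRESHOLD = 0.999

TEST_FISHER = "fisher"
TEST_CHI2 = "chi2"
TEST_KS = "ks"


class SelectionError(ValueError):
    """Raised when screening or PCA cannot proceed on the given data."""


@dataclass
class SelectionModel:
    """Result of screening (+ optionally PCA) learned on training data."""

    retained_features: list[str] = field(default_factory=list)
    test_used: dict[str, str] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    # PCA state (filled by pca_fit)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    pca_features: list[str] = field(default_factory=list)
    pca_components: np.ndarray | None = None
    explained_variance: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    k: int = 0
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD

    @property
    def fitted(self) -> bool:
        return self.pca_components is not None

    def to_json(self, path: str) -> None:
        doc = {
            "retained_features": self.retained_features,
            "test_used": self.test_used,
            "p_values": self.p_values,
            "alpha": self.alpha,
            "standardization": {
                k: list(v) for k, v in self.standardization.items()
            },
            "pca_features": self.pca_features,
            "pca_components": (
                self.pca_components.tolist()
                if self.pca_components is not None else None
            ),
            "explained_variance": (
                self.explained_variance.tolist()
                if self.explained_variance is not None else None
            ),
            "explained_variance_ratio": (
                self.explained_variance_ratio.tolist()
                if self.explained_variance_ratio is not None else None
            ),
            "k": self.k,
            "variance_threshold": self.variance_threshold,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "SelectionModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            retained_features=doc["retained_features"],
            test_used=doc["test_used"],
            p_values=doc["p_values"],
            alpha=doc["alpha"],
            standardization={
                k: (v[0], v[1]) for k, v in doc["standardization"].items()
            },
            pca_features=doc["pca_features"],
            pca_components=(
                np.asarray(doc["pca_components"])
                if doc["pca_components"] is not None else None
            ),
            explained_variance=(
                np.asarray(doc["explained_variance"])
                if doc["explained_variance"] is not None else None
            ),
            explained_variance_ratio=(
                np.asarray(doc["explained_variance_ratio"])
                if doc["explained_variance_ratio"] is not None else None
            ),
            k=doc["k"],
            variance_threshold=doc["variance_threshold"],
        )


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------

def ks_test(pos: Sequence[float], neg: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic two-sided p-value."""
    if len(pos) < 2 or len(neg) < 2:
        raise SelectionError("KS test needs at least 2 values per group")
    res = stats.ks_2samp(np.asarray(pos), np.asarray(neg), method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_test(
    feature: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Pearson chi-squared on the (count-value x class) contingency table.

    Distinct count values form the rows; values whose total occurrence is
    below 5 are pooled into an "other" row, and rows are further pooled
    (smallest total first) until all expected cells are >= 1.  A table that
    degenerates to a single row or column is flagged non-selectable via
    p = 1 (statistic 0).
    """
    x = np.asarray(feature)
    y = np.asarray(labels)
    values = np.unique(x)
    rows: list[np.ndarray] = []
    pooled = np.zeros(2)
    for v in values:
        counts = np.array([np.sum((x == v) & (y == 0)), np.sum((x == v) & (y == 1))],
                          dtype=float)
        if counts.sum() < 5:
            pooled += counts
        else:
            rows.append(counts)
    if pooled.sum() > 0:
        rows.append(pooled)

    def expected_min(table: np.ndarray) -> float:
        rs = table.sum(axis=1, keepdims=True)
        cs = table.sum(axis=0, keepdims=True)
        return float((rs * cs / table.sum()).min())

    table = np.asarray(rows, dtype=float)
    while len(table) > 1 and expected_min(table) < 1.0:
        order = np.argsort(table.sum(axis=1))
        i, j = order[0], order[1]
        merged = table[i] + table[j]
        table = np.delete(table, [i, j], axis=0)
        table = np.vstack([table, merged])
    nonzero_cols = table.sum(axis=0) > 0
    table = table[:, nonzero_cols]
    if len(table) < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def fisher_test(feature: Sequence[float], labels: Sequence[int]) -> float:
    """Two-sided Fisher's exact p for a binary feature vs binary class."""
    x = np.asarray(feature)
    y = np.asarray(labels)
    table = np.array(
        [
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x != 0) & (y == 0)), np.sum((x != 0) & (y == 1))],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def _test_for_column(name: str, category: str) -> str:
    if category == "gene_function":
        return TEST_FISHER
    if category in ("tfbs", "conserved_element") and name.endswith("_count"):
        return TEST_CHI2
    return TEST_KS


def screen(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    alpha: float = DEFAULT_ALPHA,
) -> SelectionModel:
    """Univariate screening of every feature at level ``alpha``.

    ``labels`` are binary (1 = methylated).  Returns a SelectionModel with
    per-feature tests and p-values and the retained list; PCA is unfitted.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(matrix.data):
        raise ValueError("labels length mismatch")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise SelectionError(
            f"need >= 2 islands per class (got {n_pos} pos / {n_neg} neg)"
        )
    model = SelectionModel(alpha=alpha)
    X = matrix.data
    pos_mask = y == 1
    for name in X.columns:
        col = X[name].to_numpy()
        test = _test_for_column(name, matrix.categories[name])
        if test == TEST_FISHER:
            p = fisher_test(col, y)
        elif test == TEST_CHI2:
            _, p = chi2_test(col, y)
        else:
            if np.all(col == col[0]):
                p = 1.0  # constant feature can never discriminate
            else:
                _, p = ks_test(col[pos_mask], col[~pos_mask])
        model.test_used[name] = test
        model.p_values[name] = p
        if p < alpha:
            model.retained_features.append(name)
    return model


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def components_for_threshold(
    ratios: np.ndarray, variance_threshold: float
) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches the
    threshold (with a small tolerance against floating-point round-down)."""
    cumulative = np.cumsum(np.asarray(ratios, dtype=float))
    k = int(np.searchsorted(cumulative, variance_threshold - 1e-9) + 1)
    return min(k, len(cumulative))


def pca_fit(
    model: SelectionModel,
    matrix: FeatureMatrix,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> SelectionModel:
    """Standardize the retained features and fit the PCA rotation.

    Constant retained features are dropped (with a warning) before
    standardization.  k is the smallest component count whose cumulative
    explained-variance ratio reaches ``variance_threshold``.
    """
    if not model.retained_features:
        raise SelectionError(
            "screening retained no features; cannot fit PCA "
            "(lower alpha or inspect the feature matrix)"
        )
    if len(matrix.data) < 2:
        raise SelectionError("PCA needs at least 2 rows")
    X = matrix.data[model.retained_features]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        logger.warning(
            "dropping %d constant features before PCA: %s",
            len(constant), constant[:5],
        )
    usable = [c for c in model.retained_features if c not in set(constant)]
    if not usable:
        raise SelectionError("all retained features are constant")
    Z = (X[usable] - means[usable]) / sds[usable]

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Z.to_numpy())

    ratios = pca.explained_variance_ratio_
    k = components_for_threshold(ratios, variance_threshold)

    model.standardization = {
        c: (float(means[c]), float(sds[c])) for c in usable
    }
    model.pca_features = usable
    model.pca_components = pca.components_
    model.explained_variance = pca.explained_variance_
    model.explained_variance_ratio = ratios
    model.k = k
    model.variance_threshold = variance_threshold
    return model


def transform(model: SelectionModel, matrix: FeatureMatrix) -> np.ndarray:
    """Project a feature matrix onto the first k principal components.

    Applies the stored standardization, so the same rotation transfers to
    unseen data (held-out folds, other tissues).
    """
    if not model.fitted:
        raise SelectionError("PCA not fitted; call pca_fit first")
    missing = [c for c in model.pca_features if c not in matrix.data.columns]
    if missing:
        raise SelectionError(f"matrix lacks retained feature columns {missing[:5]}")
    X = matrix.data[model.pca_features].to_numpy(dtype=float)
    mu = np.array([model.standardization[c][0] for c in model.pca_features])
    sd = np.array([model.standardization[c][1] for c in model.pca_features])
    Z = (X - mu) / sd
    return Z @ model.pca_components[: model.k].T


def inverse_transform(model: SelectionModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to standardized feature space."""
    if not model.fitted:
        raise SelectionError("PCA not fitted")
    n_comp = scores.shape[1]
    return scores @ model.pca_components[:n_comp]


def fit_selection(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    alpha: float = DEFAULT_ALPHA,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> SelectionModel:
    """Convenience: screen then PCA-fit in one call."""
    model = screen(matrix, labels, alpha=alpha)
    return pca_fit(model, matrix, variance_threshold=variance_threshold)
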