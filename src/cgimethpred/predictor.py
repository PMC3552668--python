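"""SVM modeling, evaluation metrics, repeated cross-validation and ablation.

A single soft-margin RBF-kernel SVM produces both outputs: the binary
methylation call is the classifier's class decision, and the continuous
0-100 intensity is 100 times the Platt-calibrated probability of the
methylated class.  Evaluation uses four measures:

    SP  = correctly classified unmethylated / unmethylated
    SE  = correctly classified methylated   / methylated
    ACC = correctly classified              / all
    CC  = Pearson correlation of predicted vs actual intensities

The ablation study trains 16 variants M1..M16 that drop feature categories
before screening: M1 keeps everything, M2 drops both histone categories,
M3..M9 drop the 7 non-empty subsets of {acetylation, gene function,
nucleosome}, and M10..M16 drop the same subsets plus histone methylation.

Validation repeats a k-fold partition (stratified by default) ``repeats``
times and averages the per-fold metrics; generalizability applies every
fold-trained pipeline from the training tissue to another tissue's data
and averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .feature_extractor import FeatureMatrix
from .feature_selector import (
    DEFAULT_ALPHA,
    DEFAULT_VARIANCE_THRESHOLD,
    SelectionModel,
    fit_selection,
    transform,
)

logger = logging.getLogger("cgimethpred")

#: Spec-default hyperparameter grids: cost 2^-5..2^15, width 2^-15..2^3,
#: both in steps of 2^2.
DEFAULT_COST_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))

#: Coarser grid used by the repeated-CV driver so full ablation runs stay
#: cheap; any grid can be passed explicitly.
CV_COST_GRID = tuple(2.0 ** e for e in range(-1, 10, 2))
CV_GAMMA_GRID = tuple(2.0 ** e for e in range(-9, 2, 2))

HISTONE_METHYLATION = "histone_methylation"
HISTONE_ACETYLATION = "histone_acetylation"
GENE_FUNCTION = "gene_function"
NUCLEOSOME = "nucleosome"

# the 7 non-empty subsets of {acetylation, function, nucleosome}, in the
# order the ablation tables list them
_NEW_FEATURE_SUBSETS: tuple[frozenset[str], ...] = (
    frozenset({HISTONE_ACETYLATION}),
    frozenset({GENE_FUNCTION}),
    frozenset({NUCLEOSOME}),
    frozenset({HISTONE_ACETYLATION, GENE_FUNCTION}),
    frozenset({HISTONE_ACETYLATION, NUCLEOSOME}),
    frozenset({GENE_FUNCTION, NUCLEOSOME}),
    frozenset({HISTONE_ACETYLATION, GENE_FUNCTION, NUCLEOSOME}),
)


@dataclass(frozen=True)
class VariantSpec:
    """One ablation variant: which feature categories are excluded."""

    id: str
    excluded_categories: frozenset[str]

    @classmethod
    def from_id(cls, variant_id: str) -> "VariantSpec":
        return cls(variant_id, VARIANTS[variant_id])


def _build_variants() -> dict[str, frozenset[str]]:
    variants: dict[str, frozenset[str]] = {
        "M1": frozenset(),
        "M2": frozenset({HISTONE_METHYLATION, HISTONE_ACETYLATION}),
    }
    for i, subset in enumerate(_NEW_FEATURE_SUBSETS, start=3):
        variants[f"M{i}"] = subset
    for i, subset in enumerate(_NEW_FEATURE_SUBSETS, start=10):
        variants[f"M{i}"] = subset | {HISTONE_METHYLATION}
    return variants


VARIANTS: dict[str, frozenset[str]] = _build_variants()


@dataclass
class SvmModel:
    """A fitted RBF SVM with Platt probability calibration."""

    estimator: SVC
    n_features: int
    cost: float
    gamma: float

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(binary labels, intensities in [0, 100]) for feature rows X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features}-dimensional features, "
                f"got shape {X.shape}"
            )
        labels = self.estimator.predict(X).astype(int)
        idx = list(self.estimator.classes_).index(1)
        proba = self.estimator.predict_proba(X)[:, idx]
        return labels, 100.0 * proba


def train(
    features: np.ndarray,
    labels: Sequence[int],
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
    seed: int = 0,
) -> SvmModel:
    """Fit the RBF SVM, tuning cost/width by inner grid search.

    The grid search sees only the supplied training data.  Passing
    single-element grids fixes the hyperparameters.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a 2-D array with >= 1 column")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    if len(cost_grid) == 1 and len(gamma_grid) == 1:
        best_c, best_g = cost_grid[0], gamma_grid[0]
    else:
        n_min = int(np.bincount(y).min())
        cv = StratifiedKFold(
            n_splits=min(inner_folds, max(2, n_min)),
            shuffle=True,
            random_state=seed,
        )
        search = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(cost_grid), "gamma": list(gamma_grid)},
            cv=cv,
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(X, y)
        best_c = float(search.best_params_["C"])
        best_g = float(search.best_params_["gamma"])

    est = SVC(
        kernel="rbf", C=best_c, gamma=best_g,
        probability=True, random_state=seed,
    )
    with warnings.catch_warnings():
        # class decision + Platt probability from one estimator is the
        # intended contract; sklearn 1.9 deprecation noise is irrelevant here
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    return SvmModel(
        estimator=est, n_features=X.shape[1], cost=best_c, gamma=best_g
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics(
    predicted_labels: Sequence[int],
    true_labels: Sequence[int],
    predicted_intensities: Sequence[float] | None = None,
    true_intensities: Sequence[float] | None = None,
) -> dict[str, float]:
    """SP, SE, ACC and (when intensities are given) CC.

    SP counts correct negatives among negatives, SE correct positives among
    positives; a fold with no member of one class reports NaN for the
    corresponding measure.  CC is the Pearson correlation of predicted vs
    actual intensities and errors on a zero-variance vector.
    """
    yp = np.asarray(predicted_labels, dtype=int)
    yt = np.asarray(true_labels, dtype=int)
    if yp.shape != yt.shape:
        raise ValueError("prediction/truth length mismatch")
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    correct = yp == yt
    out = {
        "SP": float(correct[yt == 0].sum() / n_neg) if n_neg else float("nan"),
        "SE": float(correct[yt == 1].sum() / n_pos) if n_pos else float("nan"),
        "ACC": float(correct.mean()),
    }
    if predicted_intensities is not None and true_intensities is not None:
        pi = np.asarray(predicted_intensities, dtype=float)
        ti = np.asarray(true_intensities, dtype=float)
        if np.std(pi) == 0 or np.std(ti) == 0:
            raise ValueError("zero-variance intensity vector: CC undefined")
        out["CC"] = float(stats.pearsonr(pi, ti)[0])
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """The pipeline trained on one training split: selection + SVM."""

    selection: SelectionModel
    svm: SvmModel
    excluded_categories: frozenset[str]

    def predict_matrix(self, matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        reduced = transform(self.selection, matrix.drop_categories(
            set(self.excluded_categories)))
        return self.svm.predict(reduced)


@dataclass
class EvaluationReport:
    """Per-fold metrics and their means for one (variant, tissue, mode)."""

    variant: str
    tissue: str
    mode: str
    seed: int
    folds: int
    repeats: int
    fold_metrics: list[dict[str, float]] = field(default_factory=list)
    skipped: dict[str, int] = field(default_factory=dict)
    models: list[FoldModel] = field(default_factory=list)

    def mean(self, key: str) -> float:
        vals = [m[key] for m in self.fold_metrics
                if key in m and not np.isnan(m[key])]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> dict[str, float]:
        return {k: self.mean(k) for k in ("SP", "SE", "ACC", "CC")}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.fold_metrics)
        df.insert(0, "variant", self.variant)
        df.insert(1, "tissue", self.tissue)
        return df


def fold_sizes(n: int, folds: int) -> list[int]:
    """Approximately equal fold sizes (e.g. 469 in 10 folds -> 46/47)."""
    base = n // folds
    extra = n % folds
    return [base + 1] * extra + [base] * (folds - extra)


def _partition(
    n: int, folds: int, rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """One random partition into folds; stratified when labels are given."""
    if labels is None:
        perm = rng.permutation(n)
        sizes = fold_sizes(n, folds)
        out = []
        at = 0
        for s in sizes:
            out.append(perm[at:at + s])
            at += s
        return out
    folds_idx: list[list[int]] = [[] for _ in range(folds)]
    offset = 0
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        for i, idx in enumerate(members):
            folds_idx[(i + offset) % folds].append(int(idx))
        offset += len(members) % folds
    return [np.asarray(sorted(f), dtype=int) for f in folds_idx]


def train_fold(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    variant: VariantSpec,
    alpha: float,
    variance_threshold: float,
    cost_grid: Sequence[float],
    gamma_grid: Sequence[float],
    seed: int,
    selection: SelectionModel | None = None,
) -> FoldModel:
    """Fit selection (unless supplied) and the SVM on one training split."""
    masked = matrix.drop_categories(set(variant.excluded_categories))
    if selection is None:
        selection = fit_selection(
            masked, labels, alpha=alpha, variance_threshold=variance_threshold
        )
    reduced = transform(selection, masked)
    svm = train(
        reduced, labels,
        cost_grid=cost_grid, gamma_grid=gamma_grid, seed=seed,
    )
    return FoldModel(
        selection=selection, svm=svm,
        excluded_categories=variant.excluded_categories,
    )


def cross_validate(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    intensities: Sequence[float],
    variant: VariantSpec | str = "M1",
    folds: int = 10,
    repeats: int = 20,
    seed: int = 0,
    mode: str = "strict",
    stratify: bool = True,
    alpha: float = DEFAULT_ALPHA,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    cost_grid: Sequence[float] = CV_COST_GRID,
    gamma_grid: Sequence[float] = CV_GAMMA_GRID,
    tissue: str = "",
    keep_models: bool = False,
) -> EvaluationReport:
    """Repeated k-fold cross-validation of one ablation variant.

    ``mode='strict'`` refits screening and PCA inside every training split
    (no information leaks into the held-out fold); ``mode='paper'`` fits
    them once on the full data set before partitioning, mirroring the
    global two-step selection the original protocol describes.  Metrics are
    averaged over folds x repeats; folds missing a class skip the undefined
    SP or SE with a logged count.  The same seed reproduces the report
    bit for bit.
    """
    if isinstance(variant, str):
        variant = VariantSpec.from_id(variant)
    if mode not in ("strict", "paper"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(labels, dtype=int)
    intens = np.asarray(intensities, dtype=float)
    n = len(y)
    if n != len(matrix.data) or n != len(intens):
        raise ValueError("matrix / labels / intensities length mismatch")

    rng = np.random.default_rng(seed)
    report = EvaluationReport(
        variant=variant.id, tissue=tissue, mode=mode,
        seed=seed, folds=folds, repeats=repeats,
        skipped={"SP": 0, "SE": 0, "CC": 0},
    )

    global_selection: SelectionModel | None = None
    if mode == "paper":
        masked = matrix.drop_categories(set(variant.excluded_categories))
        global_selection = fit_selection(
            masked, y, alpha=alpha, variance_threshold=variance_threshold
        )

    for _ in range(repeats):
        partition = _partition(n, folds, rng, labels=y if stratify else None)
        for held_out in partition:
            train_idx = np.setdiff1d(np.arange(n), held_out)
            fold_seed = int(rng.integers(0, 2**31 - 1))
            fm = train_fold(
                matrix.subset_rows([matrix.island_ids[i] for i in train_idx]),
                y[train_idx], variant, alpha, variance_threshold,
                cost_grid, gamma_grid, fold_seed,
                selection=global_selection,
            )
            test_matrix = matrix.subset_rows(
                [matrix.island_ids[i] for i in held_out]
            )
            pred_labels, pred_intens = fm.predict_matrix(test_matrix)
            m = metrics(pred_labels, y[held_out])
            m["n_pos"] = int((y[held_out] == 1).sum())
            m["n_neg"] = int((y[held_out] == 0).sum())
            ti = intens[held_out]
            pi = pred_intens
            if np.std(pi) > 0 and np.std(ti) > 0:
                m["CC"] = float(stats.pearsonr(pi, ti)[0])
            else:
                report.skipped["CC"] += 1
            for key in ("SP", "SE"):
                if np.isnan(m[key]):
                    report.skipped[key] += 1
            report.fold_metrics.append(m)
            if keep_models:
                report.models.append(fm)

    for key, count in report.skipped.items():
        if count:
            logger.info(
                "cross_validate %s: %d folds skipped for %s",
                variant.id, count, key,
            )
    return report


def generalize(
    trained: EvaluationReport | Sequence[FoldModel],
    matrix_b: FeatureMatrix,
    labels_b: Sequence[int],
    intensities_b: Sequence[float],
    tissue: str = "",
) -> EvaluationReport:
    """Apply pipelines trained on tissue A to another tissue's data.

    ``matrix_b`` must be extracted with the same manifest (for histone
    variants this means tissue A's histone tracks are substituted, per the
    cross-tissue protocol).  Every fold-trained model is applied unchanged
    and the metrics are averaged over all of them.
    """
    models = trained.models if isinstance(trained, EvaluationReport) else list(trained)
    if not models:
        raise ValueError(
            "no trained fold models (run cross_validate with keep_models=True)"
        )
    y = np.asarray(labels_b, dtype=int)
    intens = np.asarray(intensities_b, dtype=float)
    base = models[0]
    report = EvaluationReport(
        variant=(trained.variant if isinstance(trained, EvaluationReport) else ""),
        tissue=tissue, mode="generalize",
        seed=(trained.seed if isinstance(trained, EvaluationReport) else 0),
        folds=0, repeats=0, skipped={"SP": 0, "SE": 0, "CC": 0},
    )
    for fm in models:
        if fm.excluded_categories != base.excluded_categories:
            raise ValueError("fold models trained with mixed variants")
        pred_labels, pred_intens = fm.predict_matrix(matrix_b)
        m = metrics(pred_labels, y)
        if np.std(pred_intens) > 0 and np.std(intens) > 0:
            m["CC"] = float(stats.pearsonr(pred_intens, intens)[0])
        else:
            report.skipped["CC"] += 1
        report.fold_metrics.append(m)
    return report
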