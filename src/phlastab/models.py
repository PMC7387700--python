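"""Classifiers and evaluation protocols for pHLA stability prediction.

The workhorse is a class-reweighted random forest over the 210 interaction
features: 1,000 trees, Gini impurity, and floor(log2(n_features)) = 7
candidate features per split.  Gradient-boosting and logistic-regression
baselines share the same surface.  Prediction for a pHLA modeled as an
ensemble of conformations is the arithmetic mean of the per-conformation
positive-class probabilities, thresholded at 0.5.

Evaluation is AUROC under two protocols: five-fold cross-validation with
folds grouped by pHLA (conformations of one complex never straddle
train/test), and leave-one-allele-out, which holds out every example of one
HLA allele to probe pan-allele generalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.utils.validation import check_is_fitted

from .dataset import TrainingMatrix, balanced_weights
from .featurize import FeatureVector

logger = logging.getLogger(__name__)

MODEL_KINDS = ("rf", "gb", "lr")


def _max_features_log2floor(n_features: int) -> int:
    """floor(log2(n_features)) candidate features per split (7 for 210)."""
    return max(1, int(math.floor(math.log2(n_features))))


class StablePeptideClassifier(ClassifierMixin, BaseEstimator):
    """Class-reweighted classifier of stable pHLA binding.

    Parameters
    ----------
    model : {"rf", "gb", "lr"}
        Underlying learner: random forest (default), gradient boosting, or
        logistic regression.
    n_estimators : int
        Trees in the forest / boosting stages.  Default 1,000.
    max_features : int, str or None
        Candidate features per split for the forest.  The default
        ``"log2floor"`` uses floor(log2(n_features)) — 7 of the 210
        interaction features.
    bootstrap : bool
        Bootstrap resampling per tree (forest only).  Disabling it makes
        each tree's root class distribution exactly the weighted class
        distribution of the training data, which pins the interpretation
        bias term to 0.5 under balanced reweighting.
    rebalance : bool
        When no explicit ``sample_weight`` is given to :meth:`fit`, apply
        per-sample weights inversely proportional to class frequency so the
        weighted class masses are 0.5/0.5.
    learning_rate, max_depth : gradient-boosting hyperparameters.
    C : inverse regularization strength for logistic regression.
    random_state : seed for every stochastic component.

    Attributes
    ----------
    estimator_ : the fitted scikit-learn model.
    classes_ : array ``[0, 1]``.
    feature_importances_ : impurity-based importances (rf/gb only),
        normalized to sum to 1.
    """

    def __init__(
        self,
        model: str = "rf",
        n_estimators: int = 1000,
        criterion: str = "gini",
        max_features: int | str | None = "log2floor",
        bootstrap: bool = True,
        rebalance: bool = True,
        learning_rate: float = 0.1,
        max_depth: int = 3,
        C: float = 1.0,
        random_state: int = 0,
    ):
        self.model = model
        self.n_estimators = n_estimators
        self.criterion = criterion
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.rebalance = rebalance
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.C = C
        self.random_state = random_state

    def _build(self, n_features: int):
        if self.model == "rf":
            mf = self.max_features
            if mf == "log2floor":
                mf = _max_features_log2floor(n_features)
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                criterion=self.criterion,
                max_features=mf,
                bootstrap=self.bootstrap,
                random_state=self.random_state,
                n_jobs=1,
            )
        if self.model == "gb":
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                random_state=self.random_state,
            )
        if self.model == "lr":
            return LogisticRegression(C=self.C, max_iter=2000)
        raise ValueError(f"unknown model kind {self.model!r}; expected one of {MODEL_KINDS}")

    def fit(self, X, y, sample_weight: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN or infinite values")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if sample_weight is None and self.rebalance:
            sample_weight = balanced_weights(y)
        est = self._build(X.shape[1])
        est.fit(X, y, sample_weight=sample_weight)
        self.estimator_ = est
        self.classes_ = est.classes_
        self.n_features_in_ = X.shape[1]
        if hasattr(est, "feature_importances_"):
            imp = est.feature_importances_
            total = imp.sum()
            self.feature_importances_ = imp / total if total > 0 else imp
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        # stable iff P(stable) >= 0.5
        proba = self.predict_proba(X)[:, self._positive_index]
        return (proba >= 0.5).astype(int)

    @property
    def _positive_index(self) -> int:
        return int(np.flatnonzero(self.classes_ == 1)[0])

    def predict_phla(
        self, conformation_vectors: Sequence[FeatureVector] | np.ndarray
    ) -> float:
        """Probability of stable binding for one pHLA.

        The per-conformation positive-class probabilities are averaged; a
        single conformation passes through unchanged.
        """
        X = _as_matrix(conformation_vectors)
        if len(X) == 0:
            raise ValueError("need at least one conformation vector")
        return float(self.predict_proba(X)[:, self._positive_index].mean())


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(vectors)
    rows = [v.values if isinstance(v, FeatureVector) else np.asarray(v) for v in vectors]
    return np.vstack(rows) if rows else np.empty((0, 0))


def train_model(
    matrix: TrainingMatrix,
    model_kind: str = "rf",
    seed: int = 0,
    **hyperparams,
) -> StablePeptideClassifier:
    """Fit a classifier on an assembled training matrix (thin wrapper)."""
    clf = StablePeptideClassifier(model=model_kind, random_state=seed, **hyperparams)
    return clf.fit(matrix.X, matrix.y, sample_weight=matrix.sample_weight)


def predict_phla(model, conformation_vectors) -> float:
    """Ensemble-averaged probability of stable binding (thin wrapper)."""
    if isinstance(model, StablePeptideClassifier):
        return model.predict_phla(conformation_vectors)
    X = _as_matrix(conformation_vectors)
    if len(X) == 0:
        raise ValueError("need at least one conformation vector")
    pos = int(np.flatnonzero(model.classes_ == 1)[0])
    return float(model.predict_proba(X)[:, pos].mean())


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve.

    Equals the Mann–Whitney statistic: the fraction of (negative, positive)
    pairs where the positive outscores the negative, ties counted 0.5.
    Raises if only one class is present (the quantity is undefined).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


@dataclass
class EvaluationReport:
    """Per-fold or per-allele AUROC values with configuration echo."""

    aurocs: dict[str, float]
    skipped: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.aurocs.values()), dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if len(self.aurocs) else float("nan")

    @property
    def std(self) -> float:
        return float(self.values.std(ddof=0)) if len(self.aurocs) else float("nan")

    def to_dict(self) -> dict:
        return {
            "aurocs": self.aurocs,
            "mean": self.mean,
            "std": self.std,
            "skipped": self.skipped,
            "config": self.config,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": list(self.aurocs), "auroc": list(self.aurocs.values())}
        )


def _phla_level_scores(
    model: StablePeptideClassifier,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate row-level probabilities to one score and label per pHLA."""
    pos = model._positive_index
    proba = model.predict_proba(X)[:, pos]
    frame = pd.DataFrame({"group": groups, "proba": proba, "label": y})
    agg = frame.groupby("group", sort=True).agg(
        proba=("proba", "mean"), label=("label", "first")
    )
    return agg["label"].to_numpy(), agg["proba"].to_numpy()


def evaluate_cv(
    matrix: TrainingMatrix,
    model_kind: str = "rf",
    k: int = 5,
    seed: int = 0,
    grouped: bool = True,
    **hyperparams,
) -> EvaluationReport:
    """K-fold cross-validated AUROC at the pHLA level.

    Folds are grouped by pHLA so that all conformations of one complex fall
    on the same side of the split (``grouped=False`` gives plain row-level
    folds, which leak in ensemble mode and exist only for comparison).
    AUROC is computed on ensemble-averaged per-pHLA probabilities.  A fold
    whose test pHLAs are single-class is flagged, excluded from the mean
    and logged.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    X, y, groups = matrix.X, matrix.y, matrix.groups
    if grouped:
        splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y, groups=groups)
    else:
        from sklearn.model_selection import KFold

        splits = KFold(n_splits=k, shuffle=True, random_state=seed).split(X, y)

    aurocs: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for i, (train_idx, test_idx) in enumerate(splits):
        name = f"fold{i}"
        clf = StablePeptideClassifier(
            model=model_kind, random_state=seed, **hyperparams
        ).fit(X[train_idx], y[train_idx], sample_weight=balanced_weights(y[train_idx]))
        labels, scores = _phla_level_scores(clf, X[test_idx], y[test_idx], groups[test_idx])
        if len(np.unique(labels)) < 2:
            skipped[name] = "single-class test fold"
            logger.warning("%s: single-class test fold excluded from the mean", name)
            continue
        aurocs[name] = roc_auc(labels, scores)
    report = EvaluationReport(
        aurocs=aurocs,
        skipped=skipped,
        config={
            "protocol": "cv", "k": k, "model": model_kind,
            "mode": matrix.mode, "seed": seed, "grouped": grouped,
        },
    )
    logger.info("CV AUROC mean %.3f (std %.3f) over %d folds", report.mean, report.std, len(aurocs))
    return report


def evaluate_loao(
    matrix: TrainingMatrix,
    model_kind: str = "rf",
    seed: int = 0,
    **hyperparams,
) -> EvaluationReport:
    """Leave-one-allele-out AUROC.

    For each allele, every one of its examples is held out, a model is
    trained on the remaining alleles, and the held-out pHLAs are scored.
    Alleles lacking either class in their held-out set have no defined
    AUROC and are reported as skipped.
    """
    alleles = np.unique(matrix.alleles)
    if len(alleles) < 2:
        raise ValueError("leave-one-allele-out needs at least 2 alleles")
    aurocs: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for allele in alleles:
        test = matrix.alleles == allele
        y_test = matrix.y[test]
        if len(np.unique(y_test)) < 2:
            skipped[str(allele)] = "held-out allele lacks one class"
            continue
        y_train = matrix.y[~test]
        if len(np.unique(y_train)) < 2:
            skipped[str(allele)] = "remaining training data single-class"
            continue
        clf = StablePeptideClassifier(
            model=model_kind, random_state=seed, **hyperparams
        ).fit(
            matrix.X[~test], y_train, sample_weight=balanced_weights(y_train)
        )
        labels, scores = _phla_level_scores(
            clf, matrix.X[test], y_test, matrix.groups[test]
        )
        aurocs[str(allele)] = roc_auc(labels, scores)
    report = EvaluationReport(
        aurocs=aurocs,
        skipped=skipped,
        config={
            "protocol": "loao", "model": model_kind,
            "mode": matrix.mode, "seed": seed,
        },
    )
    logger.info(
        "LOAO AUROC mean %.3f over %d alleles (%d skipped)",
        report.mean, len(aurocs), len(skipped),
    )
    return report


def feature_importance(model: StablePeptideClassifier) -> np.ndarray:
    """Mean-decrease-in-impurity importances, normalized to sum to 1."""
    check_is_fitted(model, "estimator_")
    if not hasattr(model, "feature_importances_"):
        raise ValueError(f"model kind {model.model!r} has no impurity importances")
    return model.feature_importances_
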