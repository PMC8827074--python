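"""Patient-grouped linear-SVM model building for PGD3 vs PGD0-2.

The model-building procedure mirrors the small-n omics workflow it
implements:

1. patients (never individual samples) are stratified by class and split
   1:1 into a training and a test group, so paired BALF/BBA samples of one
   patient can never leak across the split;
2. a linear maximum-margin classifier is trained on all features
   (log-transformed, per-feature standardized);
3. per-feature importance is the absolute standardized weight, rescaled so
   the most discriminatory feature scores 100;
4. features with scaled importance ≥ 50 that are detected in at least 25 %
   of the samples of at least one class are retained;
5. the classifier is refitted on the retained panel and evaluated on the
   held-out patients (AUROC, confusion metrics, Platt-calibrated
   probabilities).

Two scikit-learn-compatible estimators carry the machinery:
:class:`VOCLinearClassifier` (classifier mixin) and
:class:`VOCFeatureSelector` (selector mixin); the module-level functions are
thin wrappers that speak the domain's containers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .io import FeatureTable, NEGATIVE_LABEL, POSITIVE_LABEL
from .metrics import EvalReport, evaluate_scores

logger = logging.getLogger("pgdvoc")


# ---------------------------------------------------------------------------
# grouped splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Patient-level train/test partition with the derived sample sets."""

    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    train_samples: tuple[str, ...]
    test_samples: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise ValueError("a patient appears on both sides of the split")


def patient_labels(meta: pd.DataFrame) -> pd.Series:
    """Per-patient class label (PGD3 iff the patient's grade is 3)."""
    grades = meta.groupby("patient_id")["pgd_grade"].max()
    return pd.Series(
        np.where(grades == 3, POSITIVE_LABEL, NEGATIVE_LABEL), index=grades.index
    )


def grouped_split(
    meta: pd.DataFrame, ratio: float = 0.5, seed: int = 0
) -> SplitPlan:
    """Stratified patient-level split; all samples follow their patient.

    ``ratio`` is the training fraction of patients within each class,
    rounded, and clipped so neither side of either class is empty.
    """
    labels = patient_labels(meta)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for lab in (POSITIVE_LABEL, NEGATIVE_LABEL):
        pats = sorted(labels.index[labels == lab])
        if len(pats) < 2:
            raise ValueError(f"class {lab} has fewer than 2 patients")
        perm = rng.permutation(len(pats))
        n_train = int(round(ratio * len(pats)))
        n_train = min(max(n_train, 1), len(pats) - 1)
        train += [pats[i] for i in perm[:n_train]]
        test += [pats[i] for i in perm[n_train:]]
    train_samples = tuple(meta.index[meta["patient_id"].isin(train)])
    test_samples = tuple(meta.index[meta["patient_id"].isin(test)])
    logger.info(
        "grouped_split(seed=%d): %d train / %d test patients; %d / %d samples",
        seed, len(train), len(test), len(train_samples), len(test_samples),
    )
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)),
                     train_samples, test_samples, seed)


# ---------------------------------------------------------------------------
# internal transform: log + per-feature standardization
# ---------------------------------------------------------------------------


class _LogStandardizer:
    """log(x + eps) then per-feature centering/scaling fitted on training data.

    eps is the smallest nonzero training value divided by 10, so zeros map
    below every detected peak without dominating the scale.  Constant
    features are left at 0 after centering (scale forced to 1).
    """

    def __init__(self, log_transform: bool = True):
        self.log_transform = log_transform

    def fit(self, X: np.ndarray) -> "_LogStandardizer":
        X = np.asarray(X, dtype=float)
        if self.log_transform:
            nz = X[X > 0]
            self.eps_ = float(nz.min() / 10.0) if nz.size else 1e-12
            X = np.log(X + self.eps_)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.log_transform:
            X = np.log(X + self.eps_)
        return (X - self.mean_) / self.scale_


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class VOCLinearClassifier(ClassifierMixin, BaseEstimator):
    """Linear maximum-margin classifier with Platt-calibrated probabilities.

    A hinge-loss + L2 (C-SVM) linear classifier fitted on log-standardized
    peak areas; a two-parameter logistic curve fitted to the training
    decision scores converts scores to P(positive class).  Deterministic
    given the data and ``C``.

    Parameters
    ----------
    C : float
        Inverse regularization strength of the soft margin.
    log_transform : bool
        Apply ``log(x + eps)`` before standardization (areas are
        log-normal-like); set False to model raw areas.
    pos_label : str
        Label treated as the positive class.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Weight vector on the standardized scale.
    intercept_ : float
        Bias term; the decision score of sample x is ``w·x + b``.
    classes_ : ndarray
        ``[negative, positive]`` label order used by ``predict_proba``.
    """

    def __init__(self, C: float = 1.0, log_transform: bool = True,
                 pos_label: str = POSITIVE_LABEL):
        self.C = C
        self.log_transform = log_transform
        self.pos_label = pos_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        y_pos = y == self.pos_label if y.dtype.kind in "OUS" else y.astype(bool)
        if y_pos.all() or not y_pos.any():
            raise ValueError("training data must contain both classes")
        neg = sorted(set(map(str, y[~y_pos]))) if y.dtype.kind in "OUS" else [False]
        self.classes_ = np.array([neg[0], self.pos_label], dtype=object) \
            if y.dtype.kind in "OUS" else np.array([False, True])
        self.n_features_in_ = X.shape[1]
        self._scaler = _LogStandardizer(self.log_transform).fit(X)
        Xt = self._scaler.transform(X)
        self._svc = SVC(kernel="linear", C=self.C).fit(Xt, y_pos.astype(int))
        self.coef_ = self._svc.coef_.ravel().copy()
        self.intercept_ = float(self._svc.intercept_[0])
        scores = self._svc.decision_function(Xt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._calibrator = LogisticRegression(C=1e6, max_iter=2000).fit(
                scores.reshape(-1, 1), y_pos.astype(int)
            )
        return self

    def decision_function(self, X) -> np.ndarray:
        Xt = self._scaler.transform(np.asarray(X, dtype=float))
        return self._svc.decision_function(Xt)

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X).reshape(-1, 1)
        return self._calibrator.predict_proba(scores)

    def predict(self, X):
        pos = self.predict_proba(X)[:, 1] >= 0.5
        return np.where(pos, self.classes_[1], self.classes_[0])


class VOCFeatureSelector(SelectorMixin, BaseEstimator):
    """Importance-scaled feature selection with a per-class prevalence filter.

    Fits :class:`VOCLinearClassifier` on all features, scales the absolute
    standardized weights so the largest is 100, and keeps features with
    scaled importance ≥ ``importance_cut`` that are additionally detected
    (area > 0) in at least ``prevalence_cut`` of the samples of at least one
    class.  Both boundary comparisons are inclusive.

    Attributes
    ----------
    importances_ : ndarray in [0, 100]
    prevalence_pos_, prevalence_neg_ : ndarray in [0, 1]
    support_ : boolean mask of retained features
    """

    def __init__(self, C: float = 1.0, importance_cut: float = 50.0,
                 prevalence_cut: float = 0.25, log_transform: bool = True,
                 pos_label: str = POSITIVE_LABEL):
        self.C = C
        self.importance_cut = importance_cut
        self.prevalence_cut = prevalence_cut
        self.log_transform = log_transform
        self.pos_label = pos_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        y_pos = y == self.pos_label if y.dtype.kind in "OUS" else y.astype(bool)
        self.n_features_in_ = X.shape[1]
        present = X > 0
        self.prevalence_pos_ = present[y_pos].mean(axis=0)
        self.prevalence_neg_ = present[~y_pos].mean(axis=0)
        model = VOCLinearClassifier(
            C=self.C, log_transform=self.log_transform, pos_label=self.pos_label
        ).fit(X, y)
        self.model_ = model
        self.importances_ = scale_importance(model.coef_)
        prev_ok = (self.prevalence_pos_ >= self.prevalence_cut) | (
            self.prevalence_neg_ >= self.prevalence_cut
        )
        self.support_ = (self.importances_ >= self.importance_cut) & prev_ok
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_


def scale_importance(weights: np.ndarray) -> np.ndarray:
    """Rescale |w| so the most discriminatory feature scores 100."""
    w = np.abs(np.asarray(weights, dtype=float))
    top = w.max()
    if top == 0:
        warnings.warn("all weights are zero; importances are all zero")
        return w
    return 100.0 * w / top


def prevalence_filter(
    table: FeatureTable, meta: pd.DataFrame, cut: float = 0.25
) -> pd.Series:
    """Keep features detected in ≥ ``cut`` of the samples of either class."""
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    present = table.areas.loc[meta.index] > 0
    pos = (meta["label"] == POSITIVE_LABEL).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("both classes must be represented")
    prev_pos = present[pos].mean(axis=0)
    prev_neg = present[~pos].mean(axis=0)
    return (prev_pos >= cut) | (prev_neg >= cut)


# ---------------------------------------------------------------------------
# operations on domain containers
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of importance-scaled feature selection on the training set."""

    importance: pd.Series  # feature -> [0, 100]
    prevalence_pgd3: pd.Series
    prevalence_pgd02: pd.Series
    retained: list[str]  # ordered by descending importance
    importance_cut: float
    prevalence_cut: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "importance": self.importance,
                "prevalence_pgd3": self.prevalence_pgd3,
                "prevalence_pgd02": self.prevalence_pgd02,
            }
        )
        df["retained"] = df.index.isin(self.retained)
        df.index.name = "feature_id"
        return df.sort_values("importance", ascending=False)


def train_linear_model(
    X: pd.DataFrame, y: pd.Series, C: float = 1.0, log_transform: bool = True
) -> VOCLinearClassifier:
    """Fit the linear classifier on a training slice (both classes required)."""
    return VOCLinearClassifier(C=C, log_transform=log_transform).fit(
        X.to_numpy(dtype=float), y.to_numpy()
    )


def select_features(
    table: FeatureTable,
    meta: pd.DataFrame,
    split: SplitPlan,
    C: float = 1.0,
    importance_cut: float = 50.0,
    prevalence_cut: float = 0.25,
    log_transform: bool = True,
) -> SelectionResult:
    """Run the full-feature fit + importance/prevalence selection on the
    training side of ``split``.  Prevalence is computed on training samples
    only, so no information from the held-out patients enters the panel.
    """
    train = [s for s in split.train_samples if s in table.areas.index]
    X = table.areas.loc[train]
    y = meta.loc[train, "label"]
    selector = VOCFeatureSelector(
        C=C,
        importance_cut=importance_cut,
        prevalence_cut=prevalence_cut,
        log_transform=log_transform,
    ).fit(X.to_numpy(dtype=float), y.to_numpy())
    feats = pd.Index(table.feature_ids)
    importance = pd.Series(selector.importances_, index=feats)
    retained = feats[selector.support_]
    retained = list(retained[np.argsort(-importance[retained].to_numpy(), kind="stable")])
    if not retained:
        raise ValueError(
            "no features retained; relax importance_cut or prevalence_cut"
        )
    logger.info("select_features: retained %d of %d features", len(retained), len(feats))
    return SelectionResult(
        importance=importance,
        prevalence_pgd3=pd.Series(selector.prevalence_pos_, index=feats),
        prevalence_pgd02=pd.Series(selector.prevalence_neg_, index=feats),
        retained=retained,
        importance_cut=importance_cut,
        prevalence_cut=prevalence_cut,
    )


def fit_and_evaluate(
    table: FeatureTable,
    meta: pd.DataFrame,
    selection: SelectionResult,
    split: SplitPlan,
    C: float = 1.0,
    log_transform: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[VOCLinearClassifier, EvalReport]:
    """Refit on the retained panel and evaluate on the held-out patients."""
    if not selection.retained:
        raise ValueError("retained feature set is empty")
    train = [s for s in split.train_samples if s in table.areas.index]
    test = [s for s in split.test_samples if s in table.areas.index]
    Xtr = table.areas.loc[train, selection.retained]
    ytr = meta.loc[train, "label"]
    model = train_linear_model(Xtr, ytr, C=C, log_transform=log_transform)
    report = _score_and_report(model, table, meta, selection, test,
                               n_boot=n_boot, seed=seed)
    return model, report


def evaluate_late_samples(
    model: VOCLinearClassifier,
    table: FeatureTable,
    meta: pd.DataFrame,
    selection: SelectionResult,
    split: SplitPlan,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Score late-window (6–72 h) samples with the early-window model.

    The same scoring path as the held-out evaluation; no refitting.  Late
    samples from *training* patients are excluded (and logged): a patient's
    specimens share a latent profile, so scoring them with a model fitted on
    that patient would break the grouping principle the split exists for.
    """
    late = list(meta.index[meta["time_window"] == "late"])
    late = [s for s in late if s in table.areas.index]
    train_pats = set(split.train_patients)
    n_before = len(late)
    late = [s for s in late if meta.loc[s, "patient_id"] not in train_pats]
    if n_before - len(late):
        logger.info(
            "evaluate_late_samples: excluded %d late samples from training patients",
            n_before - len(late),
        )
    if not late:
        raise ValueError("no late-window samples from held-out patients")
    return _score_and_report(model, table, meta, selection, late,
                             n_boot=n_boot, seed=seed)


def _score_and_report(model, table, meta, selection, samples,
                      n_boot=2000, seed=0) -> EvalReport:
    X = table.areas.loc[samples, selection.retained].to_numpy(dtype=float)
    scores = pd.Series(model.decision_function(X), index=samples, name="score")
    proba = pd.Series(model.predict_proba(X)[:, 1], index=samples, name="p_pgd3")
    y = meta.loc[samples, "label"]
    return evaluate_scores(scores, proba, y, n_boot=n_boot, seed=seed)
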