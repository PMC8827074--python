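"""Overfitting diagnostics: permutation nulls and validation-scheme audits.

A model selected and evaluated on 386 features and a few dozen samples can
look perfect for the wrong reasons.  Three safeguards are implemented:

* **random-feature null** — repeat train-and-predict on panels of k features
  drawn uniformly at random; an informative pipeline should beat the ~0.5
  AUROC this produces;
* **random-label null** — keep the real retained panel and scores, permute
  the test-set labels at the *patient* level (both samples of one patient
  always share a permuted label, preserving the dependence structure);
* **validation-scheme comparison** — demonstrate that no cross-validation
  and sample-level leave-one-out inflate apparent performance relative to
  the patient-grouped split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .classify import (
    SelectionResult,
    SplitPlan,
    VOCFeatureSelector,
    VOCLinearClassifier,
    patient_labels,
    train_linear_model,
)
from .io import FeatureTable, POSITIVE_LABEL
from .metrics import EvalReport, auroc

logger = logging.getLogger("pgdvoc")


@dataclass
class NullResult:
    """Empirical AUROC distribution under a permutation null."""

    auroc_draws: list[float] = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0
    n_reps: int = 0
    mode: str = ""
    seed: int = 0

    @classmethod
    def from_draws(cls, draws, mode: str, seed: int) -> "NullResult":
        arr = np.asarray(draws, dtype=float)
        if arr.size < 1:
            raise ValueError("a null needs at least one replicate")
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("AUROC draw outside [0, 1]")
        return cls(
            auroc_draws=list(arr),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            n_reps=int(arr.size),
            mode=mode,
            seed=seed,
        )

    def empirical_p(self, observed: float) -> float:
        """Fraction of null draws at or above the observed AUROC (add-one)."""
        arr = np.asarray(self.auroc_draws)
        return float((1 + (arr >= observed).sum()) / (1 + arr.size))


def _test_auroc(model: VOCLinearClassifier, X_test: np.ndarray, y_pos: np.ndarray) -> float:
    scores = model.decision_function(X_test)
    return auroc(scores[y_pos], scores[~y_pos])


def random_feature_null(
    table: FeatureTable,
    meta: pd.DataFrame,
    split: SplitPlan,
    k: int = 20,
    n_reps: int = 200,
    seed: int = 0,
    C: float = 1.0,
    log_transform: bool = True,
) -> NullResult:
    """Train-and-predict on ``n_reps`` uniformly drawn k-feature panels."""
    feats = np.asarray(table.feature_ids)
    if k > feats.size:
        raise ValueError(f"k={k} exceeds feature count {feats.size}")
    train = [s for s in split.train_samples if s in table.areas.index]
    test = [s for s in split.test_samples if s in table.areas.index]
    Xtr_all = table.areas.loc[train].to_numpy(dtype=float)
    Xte_all = table.areas.loc[test].to_numpy(dtype=float)
    ytr = meta.loc[train, "label"].to_numpy()
    yte_pos = (meta.loc[test, "label"] == POSITIVE_LABEL).to_numpy()
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_reps):
        cols = np.sort(rng.choice(feats.size, size=k, replace=False))
        model = VOCLinearClassifier(C=C, log_transform=log_transform).fit(
            Xtr_all[:, cols], ytr
        )
        draws.append(_test_auroc(model, Xte_all[:, cols], yte_pos))
    return NullResult.from_draws(draws, mode="random_feature", seed=seed)


def permute_patient_labels(
    meta: pd.DataFrame, rng: np.random.Generator, samples=None
) -> pd.Series:
    """Permute class labels across patients; samples inherit their patient's
    permuted label, so within-patient pairs stay concordant."""
    sub = meta if samples is None else meta.loc[list(samples)]
    labs = patient_labels(sub)
    permuted = pd.Series(
        rng.permutation(labs.to_numpy()), index=labs.index
    )
    return sub["patient_id"].map(permuted)


def random_label_null(
    table: FeatureTable,
    meta: pd.DataFrame,
    selection: SelectionResult,
    split: SplitPlan,
    n_reps: int = 200,
    seed: int = 0,
    C: float = 1.0,
    log_transform: bool = True,
) -> NullResult:
    """Score the real model against patient-level permuted test labels.

    The retained panel and the fitted model are fixed from the real run;
    only the test-set labels are shuffled (at the patient level).
    """
    train = [s for s in split.train_samples if s in table.areas.index]
    test = [s for s in split.test_samples if s in table.areas.index]
    model = train_linear_model(
        table.areas.loc[train, selection.retained],
        meta.loc[train, "label"],
        C=C,
        log_transform=log_transform,
    )
    scores = model.decision_function(
        table.areas.loc[test, selection.retained].to_numpy(dtype=float)
    )
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_reps):
        y = permute_patient_labels(meta, rng, samples=test)
        pos = (y == POSITIVE_LABEL).to_numpy()
        draws.append(auroc(scores[pos], scores[~pos]))
    return NullResult.from_draws(draws, mode="random_label", seed=seed)


def no_information_rate_test(report: EvalReport) -> float:
    """One-sided exact binomial test of accuracy against the majority-class
    rate (the no-information rate, NIR) of the test set."""
    n = report.n
    correct = report.tp + report.tn
    n_pos = report.tp + report.fn
    nir = max(n_pos, n - n_pos) / n
    return float(binomtest(correct, n, nir, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# validation-scheme comparison
# ---------------------------------------------------------------------------


def _apparent_auroc_none(table, meta, samples, C, log_transform,
                         importance_cut, prevalence_cut, y=None):
    """Select on all samples, refit, score the same samples (no validation)."""
    X = table.areas.loc[samples]
    y = meta.loc[samples, "label"] if y is None else y
    sel = VOCFeatureSelector(
        C=C, importance_cut=importance_cut, prevalence_cut=prevalence_cut,
        log_transform=log_transform,
    ).fit(X.to_numpy(dtype=float), y.to_numpy())
    cols = np.flatnonzero(sel.support_)
    if cols.size == 0:
        cols = np.array([int(np.argmax(sel.importances_))])
    model = VOCLinearClassifier(C=C, log_transform=log_transform).fit(
        X.to_numpy(dtype=float)[:, cols], y.to_numpy()
    )
    pos = (y == POSITIVE_LABEL).to_numpy()
    return _test_auroc(model, X.to_numpy(dtype=float)[:, cols], pos)


def _apparent_auroc_loocv(table, meta, samples, C, log_transform,
                          importance_cut, prevalence_cut, y=None):
    """Sample-level leave-one-out with selection done once on all samples.

    This is the leaky variant the grouped split exists to avoid: the panel
    sees every label, and a held-out sample's paired specimen stays in the
    training fold.
    """
    X = table.areas.loc[samples]
    y = meta.loc[samples, "label"] if y is None else y
    sel = VOCFeatureSelector(
        C=C, importance_cut=importance_cut, prevalence_cut=prevalence_cut,
        log_transform=log_transform,
    ).fit(X.to_numpy(dtype=float), y.to_numpy())
    cols = np.flatnonzero(sel.support_)
    if cols.size == 0:
        cols = np.array([int(np.argmax(sel.importances_))])
    Xv = X.to_numpy(dtype=float)[:, cols]
    yv = y.to_numpy()
    scores = np.empty(len(samples))
    for i in range(len(samples)):
        mask = np.ones(len(samples), dtype=bool)
        mask[i] = False
        if len(set(yv[mask])) < 2:
            scores[i] = 0.0
            continue
        m = VOCLinearClassifier(C=C, log_transform=log_transform).fit(
            Xv[mask], yv[mask]
        )
        scores[i] = m.decision_function(Xv[i:i + 1])[0]
    pos = yv == POSITIVE_LABEL
    return auroc(scores[pos], scores[~pos])


def _apparent_auroc_grouped(table, meta, split, C, log_transform,
                            importance_cut, prevalence_cut, y=None):
    train = [s for s in split.train_samples if s in table.areas.index]
    test = [s for s in split.test_samples if s in table.areas.index]
    ally = meta["label"] if y is None else y
    Xtr = table.areas.loc[train]
    sel = VOCFeatureSelector(
        C=C, importance_cut=importance_cut, prevalence_cut=prevalence_cut,
        log_transform=log_transform,
    ).fit(Xtr.to_numpy(dtype=float), ally.loc[train].to_numpy())
    cols = np.flatnonzero(sel.support_)
    if cols.size == 0:
        cols = np.array([int(np.argmax(sel.importances_))])
    model = VOCLinearClassifier(C=C, log_transform=log_transform).fit(
        Xtr.to_numpy(dtype=float)[:, cols], ally.loc[train].to_numpy()
    )
    pos = (ally.loc[test] == POSITIVE_LABEL).to_numpy()
    return _test_auroc(model, table.areas.loc[test].to_numpy(dtype=float)[:, cols], pos)


def compare_validation_schemes(
    table: FeatureTable,
    meta: pd.DataFrame,
    schemes=("none", "loocv", "grouped_split"),
    seed: int = 0,
    n_null: int = 20,
    C: float = 1.0,
    log_transform: bool = True,
    importance_cut: float = 50.0,
    prevalence_cut: float = 0.25,
    overfit_threshold: float = 0.6,
) -> pd.DataFrame:
    """Apparent AUROC and patient-permuted-label null mean per scheme.

    For each scheme the entire selection-and-evaluation procedure is re-run
    under patient-level permuted labels ``n_null`` times; a null mean above
    ``overfit_threshold`` flags the scheme as overfitting (an honest scheme
    cannot beat chance on shuffled labels).
    """
    from .classify import grouped_split as _gsplit

    samples = list(meta.index[meta.index.isin(table.areas.index)])
    kw = dict(C=C, log_transform=log_transform,
              importance_cut=importance_cut, prevalence_cut=prevalence_cut)
    rows = []
    for scheme in schemes:
        rng = np.random.default_rng(seed)
        if scheme == "none":
            run = lambda y=None: _apparent_auroc_none(table, meta, samples, y=y, **kw)
        elif scheme == "loocv":
            run = lambda y=None: _apparent_auroc_loocv(table, meta, samples, y=y, **kw)
        elif scheme == "grouped_split":
            split = _gsplit(meta.loc[samples], ratio=0.5, seed=seed)
            run = lambda y=None: _apparent_auroc_grouped(table, meta, split, y=y, **kw)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        apparent = run()
        nulls = []
        for _ in range(n_null):
            y_perm = permute_patient_labels(meta, rng, samples=samples)
            nulls.append(run(y=y_perm))
        null_mean = float(np.mean(nulls))
        rows.append(
            {
                "scheme": scheme,
                "apparent_auroc": apparent,
                "null_mean_auroc": null_mean,
                "overfit": null_mean > overfit_threshold,
            }
        )
        logger.info(
            "compare_validation_schemes: %s apparent %.3f null %.3f",
            scheme, apparent, null_mean,
        )
    return pd.DataFrame(rows)
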