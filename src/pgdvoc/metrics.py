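"""Classifier figures of merit: AUROC, confusion metrics, bootstrap CIs.

AUROC is computed as the Mann–Whitney concordance probability of the decision
scores — the probability that a randomly chosen positive (PGD3) sample scores
above a randomly chosen negative one, ties counted one half.  The 95 % CI is
a stratified bootstrap over test samples (positives and negatives resampled
separately), which makes no normality assumption about the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import POSITIVE_LABEL


def auroc(pos_scores, neg_scores) -> float:
    """Mann–Whitney concordance of positive vs negative decision scores."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUROC undefined: one class is empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, y_pos) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold), endpoints (0,0) and (1,1)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y_pos, dtype=int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def bootstrap_auroc_ci(
    pos_scores, neg_scores, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile stratified-bootstrap CI for the AUROC."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        n = rng.choice(neg, size=neg.size, replace=True)
        draws[b] = auroc(p, n)
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else float("nan")


@dataclass
class EvalReport:
    """Test-set evaluation of the PGD3-vs-PGD0-2 classifier.

    PGD3 is the positive class.  All confusion-derived rates follow the
    textbook identities exactly (they are computed from the counts).
    """

    auroc: float
    ci95: tuple[float, float]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    proba: pd.Series = field(repr=False)  # per-sample P(PGD3)
    scores: pd.Series = field(repr=False)  # raw decision scores
    y_true: pd.Series = field(repr=False)  # true labels

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "n_test": self.n,
        }


def evaluate_scores(
    scores: pd.Series,
    proba: pd.Series,
    y_true: pd.Series,
    n_boot: int = 2000,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Build an :class:`EvalReport` from decision scores and probabilities.

    The class call uses the calibrated probability at ``threshold``; the
    AUROC uses the raw decision scores (ranking is what matters).
    """
    y_pos = (y_true == POSITIVE_LABEL).to_numpy()
    if y_pos.all() or not y_pos.any():
        raise ValueError("test set must contain both classes")
    s = scores.to_numpy(dtype=float)
    a = auroc(s[y_pos], s[~y_pos])
    ci = bootstrap_auroc_ci(s[y_pos], s[~y_pos], n_boot=n_boot, seed=seed)
    ci = (min(ci[0], a), max(ci[1], a))
    call_pos = proba.to_numpy(dtype=float) >= threshold
    tp = int((call_pos & y_pos).sum())
    fp = int((call_pos & ~y_pos).sum())
    tn = int((~call_pos & ~y_pos).sum())
    fn = int((~call_pos & y_pos).sum())
    return EvalReport(
        auroc=a,
        ci95=ci,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        accuracy=_safe_div(tp + tn, tp + fp + tn + fn),
        proba=proba,
        scores=scores,
        y_true=y_true,
    )


def implied_prevalence_npv(sensitivity: float, specificity: float, ppv: float) -> tuple[float, float]:
    """Prevalence and NPV implied by (sensitivity, specificity, PPV).

    Bayes' identities:
    ``PPV = se·π / (se·π + (1−sp)(1−π))`` solved for the prevalence π, then
    ``NPV = sp(1−π) / (sp(1−π) + (1−se)π)``.  Useful for checking that a
    published quadruple of rates is internally consistent.
    """
    fp_rate = 1.0 - specificity
    prevalence = (ppv * fp_rate) / (ppv * fp_rate + sensitivity * (1.0 - ppv))
    npv = (specificity * (1.0 - prevalence)) / (
        specificity * (1.0 - prevalence) + (1.0 - sensitivity) * prevalence
    )
    return float(prevalence), float(npv)
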