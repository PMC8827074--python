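"""BALF–BBA agreement: is within-patient variation smaller than between?

Two airway specimens are available per patient (bronchoalveolar lavage
fluid and blind bronchial aspirate).  If the VOC profile of a patient's two
specimens agrees more than profiles of different patients within one
specimen type, the matrices may be pooled for modelling, doubling the
effective sample count.

Correlations are computed across all aligned features of a sample pair, on
``log(normalized area + eps)`` by default (areas are log-normal-like and
zeros must not dominate); ``eps`` is the smallest nonzero normalized area of
the table divided by 10.  A raw-scale option is retained behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import FeatureTable, MATRIX_TYPES, normalize_areas

logger = logging.getLogger("pgdvoc")

#: Returned when a correlation is undefined (a constant vector).
UNDEFINED_CORRELATION = float("nan")


def sample_correlation(a, b, method: str = "pearson") -> float:
    """Correlation between two samples' area vectors over aligned features.

    Pearson on values; Spearman is Pearson on average ranks (ties share
    their mean rank).  A constant vector has no defined correlation and
    yields NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("sample_correlation: constant vector, correlation undefined")
        return UNDEFINED_CORRELATION
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ConcordanceSummary:
    """Mean within-patient cross-matrix correlation vs cross-individual."""

    mean_paired_r: float
    sd_paired_r: float
    mean_balf_r: float
    sd_balf_r: float
    mean_bba_r: float
    sd_bba_r: float
    method: str
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean_paired_r": self.mean_paired_r,
            "sd_paired_r": self.sd_paired_r,
            "mean_balf_r": self.mean_balf_r,
            "sd_balf_r": self.sd_balf_r,
            "mean_bba_r": self.mean_bba_r,
            "sd_bba_r": self.sd_bba_r,
            "n_pairs": self.n_pairs,
        }


def _log_matrix(table: FeatureTable, log_scale: bool) -> np.ndarray:
    t = table if table.normalized else normalize_areas(table)
    X = t.areas.to_numpy(dtype=float)
    if not log_scale:
        return X
    nz = X[X > 0]
    eps = nz.min() / 10.0 if nz.size else 1e-12
    return np.log(X + eps)


def _pair_corr(X: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    return np.corrcoef(X)


def concordance_summary(
    table: FeatureTable,
    meta: pd.DataFrame,
    method: str = "pearson",
    log_scale: bool = True,
) -> ConcordanceSummary:
    """Summarize paired vs cross-individual sample correlations.

    Paired set: same patient, same time window, different matrix.
    Cross-individual sets: all unordered same-matrix sample pairs from
    distinct patients, each counted once.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    X = _log_matrix(table.subset(sample_ids=list(meta.index)), log_scale)
    C = _pair_corr(X, method)
    ids = list(meta.index)
    pat = meta["patient_id"].to_numpy()
    mat = meta["matrix_type"].to_numpy()
    win = meta["time_window"].to_numpy()

    paired, within = [], {m: [] for m in MATRIX_TYPES}
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = C[i, j]
            if np.isnan(r):
                continue
            if pat[i] == pat[j]:
                if mat[i] != mat[j] and win[i] == win[j]:
                    paired.append(r)
            elif mat[i] == mat[j]:
                within[mat[i]].append(r)
    if not paired:
        raise ValueError("no within-patient cross-matrix pairs available")

    def _ms(v):
        v = np.asarray(v, dtype=float)
        return (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0) \
            if v.size else (float("nan"), float("nan"))

    mp, sp = _ms(paired)
    mb, sb = _ms(within["BALF"])
    ma, sa = _ms(within["BBA"])
    return ConcordanceSummary(
        mean_paired_r=mp, sd_paired_r=sp,
        mean_balf_r=mb, sd_balf_r=sb,
        mean_bba_r=ma, sd_bba_r=sa,
        method=method, n_pairs=len(paired),
    )


def pooling_decision(summary: ConcordanceSummary) -> str:
    """``"pool"`` iff the paired mean strictly exceeds both cross-individual
    means (ties conservatively keep the matrices separate)."""
    background = max(summary.mean_balf_r, summary.mean_bba_r)
    decision = "pool" if summary.mean_paired_r > background else "keep_separate"
    logger.info(
        "pooling_decision: %s (paired %.3f vs background %.3f, margin %.3f)",
        decision, summary.mean_paired_r, background,
        summary.mean_paired_r - background,
    )
    return decision
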