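"""Clinical-covariate screening against the VOC pattern.

Covers four jobs:

* a cohort description table (continuous variables: two-sided Wilcoxon
  rank-sum; categorical: Pearson chi-squared *without* continuity
  correction) comparing PGD3 against PGD0-2 patients;
* a MANOVA screen (Pillai trace with approximate F) testing whether a
  categorical clinical factor shifts the multivariate VOC response;
* the clinical stratifiers used for that screen (BMI class, ischemia-time
  class, recipient-risk class);
* Pearson correlations between selected features and 3-month spirometry,
  with Benjamini–Hochberg adjustment across the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, f as f_dist, mannwhitneyu, pearsonr
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

from .io import POSITIVE_LABEL

logger = logging.getLogger("pgdvoc")


def _round_sig(p: float, sig: int = 2) -> float:
    if p == 0 or not np.isfinite(p):
        return p
    from math import floor, log10

    return round(p, -int(floor(log10(abs(p)))) + (sig - 1))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact when samples are small
    and tie-free, per scipy's Mann-Whitney implementation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if max(a.size, b.size) <= 25 and np.unique(
        np.concatenate([a, b])).size == a.size + b.size else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def chi_squared(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a contingency table.

    Returns (statistic, p).  The uncorrected statistic is
    ``sum((O - E)^2 / E)`` over cells.
    """
    res = chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(res.statistic), float(res.pvalue)


def cohort_table(
    records: pd.DataFrame,
    group: pd.Series,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Study-population-style group comparison of clinical variables.

    ``group`` is a per-patient label series aligned with ``records``
    (PGD3 vs PGD0-2).  Variables not listed explicitly are assigned by
    dtype: numeric columns are treated as continuous (mean (SD) summaries,
    Wilcoxon rank-sum), everything else as categorical (count (%) of the
    modal "positive" level, Pearson chi-squared without continuity
    correction).  All-missing variables are omitted with a warning; the
    reported p-value is rounded to 2 significant figures (raw p retained).
    """
    group = group.loc[records.index]
    g_pos = group == POSITIVE_LABEL
    if g_pos.sum() < 2 or (~g_pos).sum() < 2:
        raise ValueError("need at least 2 records per group")
    cols = [c for c in records.columns if c != "patient_id"]
    if continuous is None:
        continuous = [c for c in cols if pd.api.types.is_numeric_dtype(records[c])
                      and records[c].dropna().nunique() > 2]
    if categorical is None:
        categorical = [c for c in cols if c not in continuous]
    rows = []
    for var in cols:
        vals = records[var]
        if vals.dropna().empty:
            logger.warning("cohort_table: %r all-missing, omitted", var)
            continue
        if var in continuous:
            a = vals[~g_pos].dropna().to_numpy(dtype=float)
            b = vals[g_pos].dropna().to_numpy(dtype=float)
            p = wilcoxon_rank_sum(a, b)
            rows.append({
                "variable": var,
                "pgd02_summary": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                "pgd3_summary": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                "test": "wilcoxon",
                "p_raw": p,
                "p": _round_sig(p),
            })
        else:
            tab = pd.crosstab(g_pos, vals)
            if tab.shape[1] < 2:
                p, stat = 1.0, 0.0
            else:
                stat, p = chi_squared(tab.to_numpy())
            level = vals.dropna().unique()
            level = sorted(level, key=str)[-1]  # report the "yes"/highest level
            a_n = int(((vals == level) & ~g_pos).sum())
            b_n = int(((vals == level) & g_pos).sum())
            rows.append({
                "variable": var,
                "pgd02_summary": f"{a_n} ({100 * a_n / int((~g_pos).sum()):.0f}%)",
                "pgd3_summary": f"{b_n} ({100 * b_n / int(g_pos.sum()):.0f}%)",
                "test": "chi-squared",
                "p_raw": p,
                "p": _round_sig(p),
            })
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# MANOVA screen
# ---------------------------------------------------------------------------


@dataclass
class ManovaResult:
    """Pillai-trace MANOVA of one categorical factor vs the VOC response."""

    factor: str
    pillai: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    n_response: int  # response dimension actually tested (after reduction)


def manova_screen(
    response: pd.DataFrame,
    factor: pd.Series,
    factor_name: str | None = None,
) -> ManovaResult:
    """Pillai-trace MANOVA of a categorical factor against a multivariate
    VOC response.

    When the response dimension p is not small relative to the residual
    degrees of freedom (p ≥ n − g), the response is projected onto its first
    ``min(p, n − g − 1)`` principal components (fitted on the pooled data)
    to keep the error cross-product matrix full rank; the projection is
    logged.  With a single response column the test reduces exactly to the
    one-way ANOVA F-test.
    """
    factor = factor.loc[response.index].astype(str)
    levels = factor.value_counts()
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    if (levels < 2).any():
        raise ValueError("every factor level needs at least 2 samples")
    name = factor_name or (factor.name or "factor")
    Y = response.to_numpy(dtype=float)
    n, p = Y.shape
    g = len(levels)
    if p >= n - g:
        k = min(p, n - g - 1)
        logger.info("manova_screen(%s): projecting %d responses onto %d PCs", name, p, k)
        Yc = Y - Y.mean(axis=0)
        _, _, vt = np.linalg.svd(Yc, full_matrices=False)
        Y = Yc @ vt[:k].T
        p = k
    if p == 1:
        return _anova_as_manova(Y.ravel(), factor, name)
    codes = pd.get_dummies(factor, drop_first=True).to_numpy(dtype=float)
    exog = np.column_stack([np.ones(n), codes])
    mv = MANOVA(Y, exog)
    L = np.hstack([np.zeros((codes.shape[1], 1)), np.eye(codes.shape[1])])
    res = mv.mv_test(hypotheses=[("factor", L, None)])
    stat = res.results["factor"]["stat"]
    row = stat.loc["Pillai's trace"]
    return ManovaResult(
        factor=name,
        pillai=float(row["Value"]),
        f_value=float(row["F Value"]),
        df_num=float(row["Num DF"]),
        df_den=float(row["Den DF"]),
        p_value=float(row["Pr > F"]),
        n_response=p,
    )


def _anova_as_manova(y: np.ndarray, factor: pd.Series, name: str) -> ManovaResult:
    # one response: Pillai = SSB/(SSB+SSE); F identical to one-way ANOVA
    groups = [y[(factor == lev).to_numpy()] for lev in factor.unique()]
    n, g = y.size, len(groups)
    grand = y.mean()
    ssb = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    sse = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    pillai = ssb / (ssb + sse)
    df_num, df_den = g - 1, n - g
    f_value = (ssb / df_num) / (sse / df_den)
    p = float(f_dist.sf(f_value, df_num, df_den))
    return ManovaResult(name, float(pillai), float(f_value),
                        float(df_num), float(df_den), p, 1)


# ---------------------------------------------------------------------------
# clinical stratifiers
# ---------------------------------------------------------------------------


def bmi_classify(bmi: float) -> str:
    """BMI class: low < 18.5; normal 18.5–25 (inclusive); high > 25 kg/m²."""
    if not bmi > 0:
        raise ValueError("BMI must be positive")
    if bmi < 18.5:
        return "low"
    if bmi <= 25.0:
        return "normal"
    return "high"


def ischemia_stratify(hours: float) -> str:
    """Total-ischemia class: short < 6 h; medium 6–10 h (inclusive); long > 10 h."""
    if not hours > 0:
        raise ValueError("ischemia time must be positive")
    if hours < 6.0:
        return "short"
    if hours <= 10.0:
        return "medium"
    return "long"


def recipient_risk(record: pd.Series) -> str:
    """Recipient PGD risk: *low* iff normal BMI (18.5–25 kg/m²), a COPD/CF
    diagnosis, and absent-or-mild pulmonary hypertension all hold; any
    missing field is conservatively treated as high risk (with a warning)."""
    needed = ("recipient_bmi", "underlying_disease", "pulmonary_hypertension")
    if any(pd.isna(record.get(k)) for k in needed):
        logger.warning("recipient_risk: missing field(s) for %s; high by default",
                       record.get("patient_id", "?"))
        return "high"
    ok_bmi = bmi_classify(float(record["recipient_bmi"])) == "normal"
    ok_dx = record["underlying_disease"] in ("CF", "COPD-Emphysema")
    ok_ph = record["pulmonary_hypertension"] == "absent/mild"
    return "low" if (ok_bmi and ok_dx and ok_ph) else "high"


# ---------------------------------------------------------------------------
# lung-function correlations
# ---------------------------------------------------------------------------


def lung_function_correlation(
    features: pd.DataFrame,
    spirometry: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each (selected feature, spirometry measure)
    pair across patients, with Benjamini–Hochberg adjustment over the grid.

    Both frames are patient-indexed; rows are aligned on the intersection.
    Pairs with fewer than 4 complete observations or a constant vector get
    an undefined (NaN) sentinel and are excluded from the adjustment.
    """
    common = features.index.intersection(spirometry.index)
    rows = []
    for f in features.columns:
        for m in spirometry.columns:
            x = features.loc[common, f].astype(float)
            y = spirometry.loc[common, m].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 4 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                r, p = float("nan"), float("nan")
            else:
                r, p = pearsonr(x[ok], y[ok])
            rows.append({"feature_id": f, "measure": m, "n": int(ok.sum()),
                         "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    defined = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if defined.any():
        out.loc[defined, "p_adj"] = multipletests(
            out.loc[defined, "p_raw"], alpha=alpha, method="fdr_bh"
        )[1]
    out["significant"] = out["p_adj"] < alpha
    return out
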