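"""Domain containers and CSV ingestion for VOC peak-table analysis.

The analysis consumes three tables:

* a **feature table** — samples in rows, VOC features in columns, cells are
  non-negative peak areas (arbitrary units) from GC×GC-TOFMS pre-processing;
  absent peaks are stored as exact ``0`` so that "found in a sample" is the
  crisp predicate ``area > 0``;
* a **sample-metadata table** linking each sample to its patient, specimen
  matrix (bronchoalveolar lavage fluid, BALF, or blind bronchial aspirate,
  BBA), sampling window (early, < 6 h post-transplant, or late, 6–72 h) and
  primary-graft-dysfunction (PGD) grade;
* a **clinical-record table** with one row per patient (donor, recipient,
  surgical and outcome fields).

All tables are plain UTF-8 comma-separated files with a mandatory header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("pgdvoc")

#: Label given to samples from patients with grade-3 PGD (the positive class).
POSITIVE_LABEL = "PGD3"
#: Label given to samples from patients with grade 0, 1 or 2 PGD.
NEGATIVE_LABEL = "PGD0-2"

MATRIX_TYPES = ("BALF", "BBA")
TIME_WINDOWS = ("early", "late")


@dataclass
class FeatureTable:
    """Samples × VOC-features matrix of non-negative peak areas.

    Parameters
    ----------
    areas
        DataFrame with sample identifiers as index and feature identifiers
        as columns; all values are finite and ``>= 0``.
    normalized
        True once rows have been scaled to unit total area.
    """

    areas: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.areas.shape

    def validate(self) -> None:
        if self.areas.index.duplicated().any():
            dupes = self.areas.index[self.areas.index.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dupes)}")
        if self.areas.columns.duplicated().any():
            dupes = self.areas.columns[self.areas.columns.duplicated()].unique()
            raise ValueError(f"duplicate feature identifiers: {list(dupes)}")
        values = self.areas.to_numpy()
        if np.isnan(values).any():
            raise ValueError("feature table contains missing cells after ingestion")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative peak area at sample "
                f"{self.areas.index[r]!r}, feature {self.areas.columns[c]!r}"
            )
        if self.normalized:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            bad &= sums > 0  # all-zero rows are tolerated
            if bad.any():
                raise ValueError("normalized table has rows not summing to 1")

    def subset(self, sample_ids=None, feature_ids=None) -> "FeatureTable":
        """Row/column restriction preserving order of the given identifiers."""
        areas = self.areas
        if sample_ids is not None:
            areas = areas.loc[list(sample_ids)]
        if feature_ids is not None:
            areas = areas[list(feature_ids)]
        return FeatureTable(areas.copy(), normalized=self.normalized)


def read_feature_table(path) -> FeatureTable:
    """Read a samples-in-rows CSV feature table.

    The first column is the sample identifier; the remaining columns are
    numeric peak areas.  Empty cells are coerced to 0 (a logged count),
    matching the convention that an undetected peak has zero area.
    """
    # pandas silently renames duplicate header names, so vet the raw header
    try:
        import csv

        with open(path, newline="") as fh:
            header = next(csv.reader(fh))[1:]
        dupes = pd.Index(header)[pd.Index(header).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate feature identifiers: {list(dupes.unique())}")
    except (TypeError, OSError):
        pass  # non-path input; FeatureTable validation still applies
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.info("read_feature_table: coerced %d missing cells to 0", n_missing)
        df = df.fillna(0.0)
    return FeatureTable(df.astype(float))


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table to CSV at full float precision (round-trip safe)."""
    table.areas.to_csv(path)


def normalize_areas(table: FeatureTable, method: str = "total_area") -> FeatureTable:
    """Scale each sample (row) to unit total area.

    All-zero rows are left untouched and logged.  Normalizing an already
    normalized table raises, so the flag cannot silently go stale; the
    operation is idempotent in value terms (row sums of 1 renormalize to
    themselves).
    """
    if method != "total_area":
        raise ValueError(f"unknown normalization method {method!r}")
    if table.normalized:
        raise ValueError("table is already normalized")
    sums = table.areas.sum(axis=1)
    zero_rows = sums == 0
    if zero_rows.any():
        logger.warning(
            "normalize_areas: %d all-zero rows left as zeros", int(zero_rows.sum())
        )
    safe = sums.replace(0, 1.0)
    return FeatureTable(table.areas.div(safe, axis=0), normalized=True)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

META_COLUMNS = ["sample_id", "patient_id", "matrix_type", "time_window", "pgd_grade"]


def validate_sample_meta(meta: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Validate a sample-metadata frame and (re)derive the binary class label.

    ``label`` is PGD3 iff ``pgd_grade == 3``; grades 0–2 collapse to the
    PGD0-2 class.  If ``table`` is given, every table sample must have exactly
    one metadata row.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["patient_id"] = meta["patient_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad = set(meta["matrix_type"]) - set(MATRIX_TYPES)
    if bad:
        raise ValueError(f"unknown matrix_type values: {sorted(bad)}")
    bad = set(meta["time_window"]) - set(TIME_WINDOWS)
    if bad:
        raise ValueError(f"unknown time_window values: {sorted(bad)}")
    grades = meta["pgd_grade"].astype(int)
    if not grades.isin([0, 1, 2, 3]).all():
        raise ValueError("pgd_grade must be in {0,1,2,3}")
    meta["pgd_grade"] = grades
    derived = np.where(grades == 3, POSITIVE_LABEL, NEGATIVE_LABEL)
    if "label" in meta.columns and not (meta["label"] == derived).all():
        raise ValueError("label column inconsistent with pgd_grade")
    meta["label"] = derived
    if table is not None:
        have = set(meta["sample_id"])
        orphans = [s for s in table.sample_ids if s not in have]
        if orphans:
            raise ValueError(f"samples without metadata: {orphans[:5]}")
    return meta.set_index("sample_id", drop=False)


def read_sample_meta(path, table: FeatureTable | None = None) -> pd.DataFrame:
    return validate_sample_meta(pd.read_csv(path), table=table)


def read_clinical_records(path) -> pd.DataFrame:
    """Read the per-patient clinical table (study-population fields)."""
    rec = pd.read_csv(path)
    rec["patient_id"] = rec["patient_id"].astype(str)
    if rec["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical records")
    for col in [c for c in rec.columns if "bmi" in c.lower()]:
        vals = rec[col].dropna()
        if (vals <= 0).any():
            raise ValueError(f"nonpositive BMI in column {col!r}")
    if "total_ischemia_h" in rec.columns:
        vals = rec["total_ischemia_h"].dropna()
        if (vals <= 0).any():
            raise ValueError("nonpositive ischemia time")
    return rec.set_index("patient_id", drop=False)


# ---------------------------------------------------------------------------
# class-wise abundance summaries and annotation
# ---------------------------------------------------------------------------


def class_abundance_ratio(
    table: FeatureTable,
    meta: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature ratio of class mean areas (PGD3 mean ÷ PGD0-2 mean).

    A ratio above 1 means the compound is, on average, more abundant in
    severe-PGD samples.  A zero PGD0-2 mean with a nonzero PGD3 mean yields
    ``inf`` with ``undefined=True``; 0/0 yields ``nan`` with the same flag.
    """
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    if features is None:
        features = table.feature_ids
    areas = table.areas.loc[meta.index, list(features)]
    pos = meta["label"] == POSITIVE_LABEL
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both PGD classes must be represented")
    mean_pos = areas[pos.to_numpy()].mean(axis=0)
    mean_neg = areas[(~pos).to_numpy()].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_pos / mean_neg
    out = pd.DataFrame(
        {
            "mean_pgd3": mean_pos,
            "mean_pgd02": mean_neg,
            "ratio": ratio,
            "undefined": mean_neg == 0,
        }
    )
    out.index.name = "feature_id"
    return out


def annotate_features(
    features: list[str],
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join putative compound names / chemical families onto a feature list.

    ``annotation`` has columns ``feature_id``, ``name``, ``family``.  Features
    without an entry are labelled ``unknown``; annotation rows referencing
    features outside ``features`` produce a warning, not an error.  Feature
    order is preserved.
    """
    out = pd.DataFrame(
        {"feature_id": list(features), "name": "unknown", "family": "unknown"}
    ).set_index("feature_id")
    if annotation is not None and len(annotation):
        ann = annotation.copy()
        ann["feature_id"] = ann["feature_id"].astype(str)
        stray = set(ann["feature_id"]) - set(out.index)
        if stray:
            logger.warning(
                "annotate_features: %d annotation rows reference unknown features",
                len(stray),
            )
        ann = ann[ann["feature_id"].isin(out.index)].set_index("feature_id")
        out.loc[ann.index, "name"] = ann["name"].fillna("unknown")
        out.loc[ann.index, "family"] = ann["family"].fillna("unknown")
    out = out.reset_index()
    counts = out["family"].value_counts()
    logger.info("annotate_features: family counts %s", counts.to_dict())
    return out


def family_counts(annotated: pd.DataFrame) -> pd.Series:
    """Tally of chemical families in an annotated feature table."""
    return annotated["family"].value_counts()
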