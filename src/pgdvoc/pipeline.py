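"""End-to-end orchestration: concordance → split → selection → evaluation →
permutation nulls → covariate screen, with a provenance-stamped report.

All randomness flows from one master seed, split per stage with
``numpy.random.SeedSequence``, so a run is fully reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import evaluate_late_samples, fit_and_evaluate, grouped_split, select_features
from .concordance import concordance_summary, pooling_decision
from .covariates import cohort_table, lung_function_correlation, manova_screen, recipient_risk
from .io import (
    FeatureTable,
    annotate_features,
    class_abundance_ratio,
    normalize_areas,
    read_clinical_records,
    read_feature_table,
    read_sample_meta,
)
from .metrics import roc_points
from .validation import no_information_rate_test, random_feature_null, random_label_null

logger = logging.getLogger("pgdvoc")

_SPIROMETRY = ["fvc_pct", "fev1_pct", "mefr_pct", "mifr_pct",
               "fef75_pct", "fef50_pct", "fef25_pct", "fev1_fvc_ratio"]


@dataclass
class RunConfig:
    """Strictly validated pipeline configuration (YAML-loadable)."""

    features_csv: str | None = None
    meta_csv: str | None = None
    records_csv: str | None = None
    annotation_csv: str | None = None
    seed: int = 0
    train_ratio: float = 0.5
    C: float = 1.0
    importance_cut: float = 50.0
    prevalence_cut: float = 0.25
    log_transform: bool = True
    n_boot: int = 2000
    n_permutations: int = 200
    k_random_features: int = 20
    run_concordance: bool = True
    run_nulls: bool = True
    run_covariates: bool = True
    run_late: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(
    config: RunConfig,
    out_dir,
    table: FeatureTable | None = None,
    meta: pd.DataFrame | None = None,
    records: pd.DataFrame | None = None,
) -> dict:
    """Execute the full workflow and write the report bundle to ``out_dir``.

    Inputs may be passed in memory or read from the paths in ``config``.
    Returns the bundle as a dict (also serialized to JSON/CSVs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = read_feature_table(config.features_csv)
    if meta is None:
        meta = read_sample_meta(config.meta_csv, table=table)
    if records is None and config.records_csv:
        records = read_clinical_records(config.records_csv)

    seeds = np.random.SeedSequence(config.seed).spawn(5)
    stage_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds]

    norm = table if table.normalized else normalize_areas(table)
    early_meta = meta[meta["time_window"] == "early"]
    from . import __version__

    bundle: dict = {
        "provenance": {
            "package_version": __version__,
            "config": asdict(config),
            "config_digest": config.digest(),
            "master_seed": config.seed,
            "stage_seeds": stage_seed,
        }
    }

    if config.run_concordance:
        conc = {}
        for method in ("pearson", "spearman"):
            s = concordance_summary(norm.subset(sample_ids=list(early_meta.index)),
                                    early_meta, method=method)
            conc[method] = s.to_dict()
        conc["decision"] = pooling_decision(
            concordance_summary(norm.subset(sample_ids=list(early_meta.index)),
                                early_meta, method="pearson")
        )
        bundle["concordance"] = conc
        pd.DataFrame([conc["pearson"], conc["spearman"]]).to_csv(
            out / "concordance.csv", index=False)

    split = grouped_split(early_meta, ratio=config.train_ratio, seed=stage_seed[0])
    selection = select_features(
        norm, early_meta, split, C=config.C,
        importance_cut=config.importance_cut,
        prevalence_cut=config.prevalence_cut,
        log_transform=config.log_transform,
    )
    model, report = fit_and_evaluate(
        norm, early_meta, selection, split, C=config.C,
        log_transform=config.log_transform,
        n_boot=config.n_boot, seed=stage_seed[1],
    )
    bundle["split"] = {
        "train_patients": list(split.train_patients),
        "test_patients": list(split.test_patients),
    }
    bundle["selection"] = {"n_retained": len(selection.retained),
                           "retained": selection.retained}
    bundle["evaluation"] = report.to_dict()
    bundle["evaluation"]["nir_p"] = no_information_rate_test(report)
    selection.to_frame().to_csv(out / "selection.csv")
    y_pos = (report.y_true == "PGD3").to_numpy()
    roc_points(report.scores, y_pos).to_csv(out / "roc.csv", index=False)
    per_sample = pd.DataFrame({
        "score": report.scores, "p_pgd3": report.proba,
        "label": report.y_true,
        "pgd_grade": meta.loc[report.y_true.index, "pgd_grade"],
    })
    per_sample["call"] = np.where(per_sample["p_pgd3"] >= 0.5, "PGD3", "PGD0-2")
    per_sample["misclassified"] = per_sample["call"] != per_sample["label"]
    per_sample.to_csv(out / "per_sample.csv")
    bundle["per_sample_csv"] = "per_sample.csv"

    if config.run_late and (meta["time_window"] == "late").any():
        try:
            late = evaluate_late_samples(model, norm, meta, selection, split,
                                         n_boot=config.n_boot, seed=stage_seed[1])
            bundle["late_evaluation"] = late.to_dict()
        except ValueError as exc:  # e.g. held-out late set missing a class
            logger.warning("late evaluation skipped: %s", exc)

    ratios = class_abundance_ratio(norm, early_meta, features=selection.retained)
    annotation = None
    if config.annotation_csv:
        annotation = pd.read_csv(config.annotation_csv)
    ann = annotate_features(selection.retained, annotation).set_index("feature_id")
    ratio_table = ratios.join(ann)
    ratio_table["importance"] = selection.importance[ratio_table.index]
    ratio_table = ratio_table.sort_values("importance", ascending=False)
    ratio_table.to_csv(out / "abundance_ratios.csv")
    bundle["abundance_ratios_csv"] = "abundance_ratios.csv"

    if config.run_nulls:
        rf = random_feature_null(norm, early_meta, split,
                                 k=config.k_random_features,
                                 n_reps=config.n_permutations,
                                 seed=stage_seed[2], C=config.C,
                                 log_transform=config.log_transform)
        rl = random_label_null(norm, early_meta, selection, split,
                               n_reps=config.n_permutations,
                               seed=stage_seed[3], C=config.C,
                               log_transform=config.log_transform)
        bundle["nulls"] = {
            "random_feature": {"mean": rf.mean, "sd": rf.sd, "n_reps": rf.n_reps},
            "random_label": {"mean": rl.mean, "sd": rl.sd, "n_reps": rl.n_reps},
        }
        pd.DataFrame({"random_feature": rf.auroc_draws,
                      "random_label": rl.auroc_draws}).to_csv(
            out / "null_draws.csv", index=False)

    if config.run_covariates and records is not None:
        group = pd.Series(
            np.where(records.get("pgd_grade",
                     _patient_grades(meta, records)) == 3, "PGD3", "PGD0-2"),
            index=records.index)
        drop = [c for c in ("pgd_grade",) if c in records.columns]
        ct = cohort_table(records.drop(columns=drop), group)
        ct.to_csv(out / "cohort_table.csv")
        manova_rows = []
        sel_patient = _patient_level_features(norm, early_meta, selection.retained)
        common = sel_patient.index.intersection(records.index)
        factors = {
            "ocs": records.loc[common, "ocs"].astype(str) if "ocs" in records else None,
            "recipient_risk": records.loc[common].apply(recipient_risk, axis=1)
            if {"recipient_bmi", "underlying_disease",
                "pulmonary_hypertension"} <= set(records.columns) else None,
        }
        for name, fac in factors.items():
            if fac is None or fac.nunique() < 2 or fac.value_counts().min() < 2:
                continue
            res = manova_screen(sel_patient.loc[common], fac, factor_name=name)
            manova_rows.append(vars(res))
        if manova_rows:
            pd.DataFrame(manova_rows).to_csv(out / "manova.csv", index=False)
            bundle["manova"] = manova_rows
        spiro_cols = [c for c in _SPIROMETRY if c in records.columns]
        if spiro_cols:
            lf = lung_function_correlation(sel_patient.loc[common],
                                           records.loc[common, spiro_cols])
            lf.to_csv(out / "lung_function.csv", index=False)
            bundle["lung_function_significant"] = int(lf["significant"].sum())
        bundle["cohort_table_csv"] = "cohort_table.csv"

    (out / "report.json").write_text(json.dumps(bundle, indent=2, default=str))
    (out / "report.md").write_text(render_report(bundle, out))
    logger.info("run_pipeline: bundle written to %s", out)
    return bundle


def _patient_grades(meta: pd.DataFrame, records: pd.DataFrame) -> np.ndarray:
    grades = meta.groupby("patient_id")["pgd_grade"].max()
    return grades.reindex(records.index).to_numpy()


def _patient_level_features(table: FeatureTable, meta: pd.DataFrame,
                            features: list[str]) -> pd.DataFrame:
    """Per-patient mean of selected features over that patient's samples."""
    areas = table.areas.loc[meta.index, features]
    return areas.groupby(meta["patient_id"]).mean()


def render_report(bundle: dict, out_dir) -> str:
    """Human-readable markdown summary of a completed bundle.

    Every number is read from the bundle / stage CSVs; nothing is
    recomputed here.
    """
    out = Path(out_dir)
    lines = ["# VOC–PGD pipeline report", ""]
    prov = bundle["provenance"]
    lines += [f"Package version {prov['package_version']}, "
              f"config digest `{prov['config_digest']}`, "
              f"master seed {prov['master_seed']}.", ""]
    if "concordance" in bundle:
        c = bundle["concordance"]["pearson"]
        lines += ["## BALF–BBA concordance",
                  f"Paired within-patient mean r = {c['mean_paired_r']:.2f}; "
                  f"cross-individual BALF {c['mean_balf_r']:.2f}, "
                  f"BBA {c['mean_bba_r']:.2f} "
                  f"→ decision: **{bundle['concordance']['decision']}**.", ""]
    ev = bundle["evaluation"]
    lines += ["## Held-out evaluation (early window)",
              f"AUROC {ev['auroc']:.2f} (95% CI {ev['ci95_lo']:.2f}–{ev['ci95_hi']:.2f}), "
              f"accuracy {ev['accuracy']:.2f}, sensitivity {ev['sensitivity']:.2f}, "
              f"specificity {ev['specificity']:.2f}, PPV {ev['ppv']:.2f}, "
              f"NPV {ev['npv']:.2f}; NIR p = {ev['nir_p']:.3g}.",
              "",
              "| | called PGD3 | called PGD0-2 |",
              "|---|---|---|",
              f"| true PGD3 | {ev['tp']} | {ev['fn']} |",
              f"| true PGD0-2 | {ev['fp']} | {ev['tn']} |", ""]
    if "late_evaluation" in bundle:
        lv = bundle["late_evaluation"]
        lines += [f"Late-window (6–72 h) AUROC {lv['auroc']:.2f} "
                  f"on {lv['n_test']} samples.", ""]
    lines += [f"## Selected panel ({bundle['selection']['n_retained']} features)", ""]
    ratio_csv = out / bundle.get("abundance_ratios_csv", "abundance_ratios.csv")
    if ratio_csv.exists():
        rt = pd.read_csv(ratio_csv)
        lines += ["| feature | importance | PGD3/PGD0-2 ratio | family |",
                  "|---|---|---|---|"]
        for _, r in rt.iterrows():
            lines.append(f"| {r['feature_id']} | {r['importance']:.0f} "
                         f"| {r['ratio']:.2f} | {r['family']} |")
        lines.append("")
    ps_csv = out / bundle.get("per_sample_csv", "per_sample.csv")
    if ps_csv.exists():
        ps = pd.read_csv(ps_csv, index_col=0)
        flagged = ps[ps["misclassified"]]
        lines += ["## Per-sample classification",
                  f"{len(flagged)} of {len(ps)} test samples misclassified."]
        if len(flagged):
            lines += ["", "| sample | grade | P(PGD3) | label |", "|---|---|---|---|"]
            for sid, r in flagged.iterrows():
                lines.append(f"| {sid} | {r['pgd_grade']} | {r['p_pgd3']:.2f} "
                             f"| {r['label']} |")
        lines.append("")
    if "nulls" in bundle:
        nl = bundle["nulls"]
        lines += ["## Permutation nulls",
                  f"Random-feature null mean AUROC "
                  f"{nl['random_feature']['mean']:.2f} "
                  f"({nl['random_feature']['n_reps']} reps); "
                  f"random-label null mean "
                  f"{nl['random_label']['mean']:.2f} "
                  f"({nl['random_label']['n_reps']} reps).", ""]
    if "manova" in bundle:
        lines += ["## Covariate screen (MANOVA, Pillai trace)", "",
                  "| factor | Pillai | F | df | p |", "|---|---|---|---|---|"]
        for row in bundle["manova"]:
            lines.append(f"| {row['factor']} | {row['pillai']:.3f} "
                         f"| {row['f_value']:.2f} "
                         f"| {row['df_num']:.0f}, {row['df_den']:.0f} "
                         f"| {row['p_value']:.3g} |")
        lines.append("")
    return "\n".join(lines)
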