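"""End-to-end orchestration: simulate -> features -> scoring -> stats -> prediction.

Every run is driven by a :class:`RunConfig` and a single seed; identical
(config, seed) produce byte-identical artifact bundles.  A ``manifest.json``
records the configuration, the seed and a SHA-256 checksum of every output
file.  Stage logging reports per-stage row counts (patients per visit), so
dropout can be accounted for the way study flow diagrams do.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SyntheticCohort, default_config, generate_cohort
from .features import (
    RAW_VISIT_COLUMNS,
    change_scores_table,
    visit_features_table,
)
from .group_stats import build_group_tables, format_group_table
from .pathology import RAW_PATIENT_COLUMNS, score_pathology_table
from .prediction import (
    MODEL_SPECS,
    feature_matrix,
    run_model_suite,
    summarize_model_suite,
)

__all__ = ["RunConfig", "ValidationReport", "run_pipeline", "validate_input"]

log = logging.getLogger("swe_response")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``synthetic=True`` (optionally with a cohort-config YAML path) or
    both input CSV paths must be given.  All randomness (cohort generation,
    missingness, bootstrap CIs) flows from ``seed``.
    """

    out_dir: str
    seed: int
    synthetic: bool = True
    cohort_config: Optional[str] = None
    visits_csv: Optional[str] = None
    patients_csv: Optional[str] = None
    ratio_scale: str = "elasticity"
    ci_boot: int = 2000
    models: str = "noninvasive,mixed"

    def resolved_cohort_config(self) -> CohortConfig:
        if self.cohort_config:
            return CohortConfig.from_yaml(self.cohort_config)
        return default_config()


@dataclass
class ValidationReport:
    passed: bool
    violations: pd.DataFrame

    def __str__(self) -> str:
        if self.passed:
            return "validation passed"
        return f"validation FAILED ({len(self.violations)} violations)"


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def _check(cond: bool, rows: list, row, column: str, message: str) -> None:
    if not cond:
        rows.append({"row": row, "column": column, "message": message})


def validate_input(csv_path, schema: str) -> ValidationReport:
    """Validate a raw CSV against the ``visits`` or ``patients`` schema.

    Checks column presence, value ranges (speeds >= 0, percentages in
    [0, 100], visit in {1, 2, 3}), duplicate (patient, visit) pairs and the
    three-tumor-ROI protocol.  Returns a per-violation report.
    """
    df = pd.read_csv(csv_path)
    rows: list = []
    if schema == "visits":
        required = RAW_VISIT_COLUMNS
    elif schema == "patients":
        required = RAW_PATIENT_COLUMNS
    else:
        raise ValueError(f"unknown schema {schema!r}")
    for col in required:
        _check(col in df.columns, rows, -1, col, "required column missing")
    if rows:
        return ValidationReport(False, pd.DataFrame(rows))

    if schema == "visits":
        for i, r in df.iterrows():
            _check(r["visit"] in (1, 2, 3), rows, i, "visit", "visit must be 1, 2 or 3")
            if pd.notna(r["mass_size_mm"]):
                _check(r["mass_size_mm"] > 0, rows, i, "mass_size_mm",
                       "mass size must be positive")
            for col in df.columns:
                if "sws" in col and pd.notna(r[col]):
                    _check(r[col] >= 0, rows, i, col, "shear-wave speed must be >= 0")
            n_rois = sum(
                pd.notna(r[f"roi{j}_sws_mean"]) for j in (1, 2, 3)
            )
            _check(n_rois in (0, 3), rows, i, "tumor_rois",
                   f"visits need exactly 3 tumor ROIs (found {n_rois})")
        dups = df.duplicated(subset=["patient_id", "visit"])
        for i in df.index[dups]:
            _check(False, rows, int(i), "patient_id",
                   "duplicate (patient, visit) record")
    else:
        for i, r in df.iterrows():
            for col in ("er_pct", "pr_pct", "ki67_pct"):
                if pd.notna(r[col]):
                    _check(0 <= r[col] <= 100, rows, i, col,
                           "percentage must lie in [0, 100]")
            _check(str(r["her2_ihc"]) in ("0", "1+", "2+", "3+"), rows, i,
                   "her2_ihc", "invalid HER2 IHC score")
            if not bool(r.get("no_surgery", False)):
                if pd.notna(r["f_inv"]):
                    _check(0 <= r["f_inv"] <= 1, rows, i, "f_inv",
                           "f_inv must lie in [0, 1]")
                if pd.notna(r["ln_pos"]):
                    _check(r["ln_pos"] >= 0, rows, i, "ln_pos",
                           "positive-node count must be >= 0")
    violations = pd.DataFrame(rows, columns=["row", "column", "message"])
    return ValidationReport(len(violations) == 0, violations)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _plot_rocs(results: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in sorted(results.items()):
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the artifact bundle.

    Returns a manifest dict (also written to ``manifest.json``) mapping every
    artifact to its SHA-256 checksum.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _write_csv(df, path)
        artifacts[name] = path

    # -- stage 1: inputs ----------------------------------------------------
    if config.synthetic:
        cc = config.resolved_cohort_config()
        cohort = generate_cohort(cc, seed=config.seed)
        visits = cohort.visits
        patients_raw = cohort.patients[RAW_PATIENT_COLUMNS]
        save(visits, "cohort_visits.csv")
        save(patients_raw, "cohort_patients.csv")
        save(cohort.truth, "cohort_truth.csv")
        save(
            cohort.patients[
                ["patient_id", "group", "true_subtype", "true_rcb_score",
                 "true_rcb_category", "true_responder"]
            ],
            "cohort_ground_truth_labels.csv",
        )
    else:
        if not (config.visits_csv and config.patients_csv):
            raise ValueError("non-synthetic runs need visits_csv and patients_csv")
        for path, schema in ((config.visits_csv, "visits"),
                             (config.patients_csv, "patients")):
            report = validate_input(path, schema)
            if not report.passed:
                raise ValueError(
                    f"{path} failed {schema} validation:\n"
                    + report.violations.to_string(index=False)
                )
        visits = pd.read_csv(config.visits_csv)
        patients_raw = pd.read_csv(config.patients_csv)
    log.info("stage inputs: %d visit rows, %d patients",
             len(visits), len(patients_raw))
    for v in (1, 2, 3):
        n_swe = visits.loc[visits["visit"] == v, "roi1_sws_mean"].notna().sum()
        log.info("  visit %d: %d patients with SWE data", v, n_swe)

    # -- stage 2: features --------------------------------------------------
    features = visit_features_table(visits, ratio_scale=config.ratio_scale)
    changes = change_scores_table(features)
    save(features, "features_visits.csv")
    save(changes, "change_scores.csv")
    log.info("stage features: %d rows, %d change-score rows",
             len(features), len(changes))

    # -- stage 3: pathology scoring ------------------------------------------
    pathology = score_pathology_table(patients_raw)
    save(pathology, "pathology_scores.csv")
    log.info("stage pathology: %d responders / %d non-responders",
             int(pathology["responder"].sum()),
             int((~pathology["responder"]).sum()))

    # -- stage 4: group tables ----------------------------------------------
    labels = pathology[["patient_id", "responder"]]
    categorical = pathology[["patient_id", "subtype", "er_pos", "pr_pos"]].copy()
    her2 = pathology["her2_pos"]
    categorical["her2_pos"] = her2.map(
        lambda x: "" if pd.isna(x) else ("pos" if x else "neg")
    )
    summary = build_group_tables(features, labels, change_scores=changes,
                                 categorical=categorical)
    save(summary, "group_summary.csv")
    (out / "group_summary.md").write_text(format_group_table(summary))
    artifacts["group_summary.md"] = out / "group_summary.md"
    log.info("stage stats: %d comparison rows", len(summary))

    # -- stage 5: prediction -------------------------------------------------
    matrix = feature_matrix(features, pathology)
    wanted = config.models.split(",")
    specs = [
        s for s in MODEL_SPECS
        if ("noninvasive" in wanted and s.name.startswith("noninvasive"))
        or ("mixed" in wanted and s.name.startswith("mixed"))
    ]
    results = run_model_suite(
        matrix, specs=specs, ci_boot=config.ci_boot, seed=config.seed
    )
    model_summary = summarize_model_suite(results)
    save(model_summary, "model_summary.csv")
    for name, r in results.items():
        save(
            pd.DataFrame({"fpr": r.fpr, "tpr": r.tpr, "threshold": r.thresholds}),
            f"roc_points_{name}.csv",
        )
    _plot_rocs(results, out / "roc_curves.png")
    artifacts["roc_curves.png"] = out / "roc_curves.png"
    log.info("stage prediction: %d models fitted", len(results))

    # -- manifest -------------------------------------------------------------
    cfg_record = asdict(config)
    cfg_record.pop("out_dir")  # bundle identity must not depend on its location
    manifest = {
        "seed": config.seed,
        "config": cfg_record,
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
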