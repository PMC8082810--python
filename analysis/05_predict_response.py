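"""Leave-one-out cross-validated response prediction.

Fits the six preset models — three noninvasive (per-visit SWE feature
pairs, all patients) and three mixed (+ Ki-67, ER-positive subset) — via
LOOCV logistic regression, and reports AUC with bootstrap 95% CI, the
ROC point closest to (0, 1), and its sensitivity/specificity.  Also
compares the visit-1 and visit-3 noninvasive AUCs with DeLong's test.

Run after 02 and 03:  python analysis/05_predict_response.py
"""

from pathlib import Path

import pandas as pd

from swe_response.prediction import (
    compare_aucs,
    feature_matrix,
    run_model_suite,
    summarize_model_suite,
)

SEED = 7
OUT = Path("results/prediction")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    features = pd.read_csv("results/features/features_visits.csv")
    pathology = pd.read_csv("results/pathology/pathology_scores.csv")
    matrix = feature_matrix(features, pathology)

    results = run_model_suite(matrix, seed=SEED)
    report = summarize_model_suite(results)
    report.to_csv(OUT / "model_summary.csv", index=False)
    for name, r in results.items():
        pd.DataFrame(
            {"fpr": r.fpr, "tpr": r.tpr, "threshold": r.thresholds}
        ).to_csv(OUT / f"roc_points_{name}.csv", index=False)

    print("LOOCV model report (AUC [95% CI], cutoff, spec, sens, n):")
    for _, r in report.iterrows():
        print(f"  {r['model']:<15s} {r['auc']:.2f} "
              f"[{r['auc_ci_lo']:.2f}-{r['auc_ci_hi']:.2f}]  "
              f"cutoff {r['cutoff']:.2f}  spec {r['specificity']:.2f}  "
              f"sens {r['sensitivity']:.2f}  n={int(r['n'])}")
    p13 = compare_aucs(results["noninvasive_v1"], results["noninvasive_v3"])
    print(f"DeLong p, noninvasive visit 1 vs visit 3: {p13:.3f}")
    print(f"wrote {OUT}/model_summary.csv and per-model ROC points")


if __name__ == "__main__":
    main()
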