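"""Compare responders and non-responders.

Builds the per-variable, per-visit summary table (complete-case n,
mean ± SD per group) with Kruskal-Wallis p-values for the continuous
SWE/MRI variables and chi-squared p-values for the categorical biomarkers.

Run after 02 and 03:  python analysis/04_compare_groups.py
"""

from pathlib import Path

import pandas as pd

from swe_response.group_stats import build_group_tables, format_group_table

OUT = Path("results/group_comparison")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    features = pd.read_csv("results/features/features_visits.csv")
    changes = pd.read_csv("results/features/change_scores.csv")
    pathology = pd.read_csv("results/pathology/pathology_scores.csv")
    labels = pathology[["patient_id", "responder"]]
    categorical = pathology[["patient_id", "subtype", "er_pos", "pr_pos"]]

    summary = build_group_tables(
        features, labels, change_scores=changes, categorical=categorical
    )
    summary.to_csv(OUT / "group_summary.csv", index=False)
    (OUT / "group_summary.md").write_text(format_group_table(summary))

    sig = summary[summary["significant"]]
    print(f"compared {len(summary)} variables; "
          f"{len(sig)} significant at p < 0.05:")
    for _, r in sig.iterrows():
        print(f"  {r['variable']:<16s} p = {r['p_value']:.4f}")
    print(f"wrote {OUT}/group_summary.csv and group_summary.md")


if __name__ == "__main__":
    main()
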