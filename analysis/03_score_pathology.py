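"""Score surgical pathology and biomarkers.

Computes each patient's residual cancer burden (RCB) score and category,
the responder label (RCB 0/I vs II/III or no surgery), ER/PR/HER2 marker
statuses, and the St. Gallen molecular subtype.

Run after 01_simulate_cohort.py:  python analysis/03_score_pathology.py
"""

from pathlib import Path

import pandas as pd

from swe_response.pathology import score_pathology_table

IN = Path("results/cohort")
OUT = Path("results/pathology")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    patients = pd.read_csv(IN / "cohort_patients.csv")
    scored = score_pathology_table(patients)
    scored.to_csv(OUT / "pathology_scores.csv", index=False)

    n_resp = int(scored["responder"].sum())
    print(f"scored {len(scored)} patients: {n_resp} responders, "
          f"{len(scored) - n_resp} non-responders "
          f"({int(scored['no_surgery'].sum())} without surgery)")
    print("RCB categories:",
          scored["rcb_category"].replace("", "none").value_counts().to_dict())
    print("subtypes:", scored["subtype"].value_counts().to_dict())
    print(f"wrote {OUT}/pathology_scores.csv")


if __name__ == "__main__":
    main()
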