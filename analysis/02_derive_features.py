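"""Derive SWE/MRI features per visit.

Converts the raw ROI shear-wave speeds to elasticity (E = 3*rho*c^2),
averages the three tumor ROIs, forms tumor-to-normal elasticity ratios, the
mass characteristic frequency f_mass = 1000*V_min/d, MRI volume, and the
earlier-minus-later change scores.

Run after 01_simulate_cohort.py:  python analysis/02_derive_features.py
"""

from pathlib import Path

import pandas as pd

from swe_response.features import change_scores_table, visit_features_table

IN = Path("results/cohort")
OUT = Path("results/features")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(IN / "cohort_visits.csv")
    features = visit_features_table(raw)
    changes = change_scores_table(features)
    features.to_csv(OUT / "features_visits.csv", index=False)
    changes.to_csv(OUT / "change_scores.csv", index=False)

    print(f"derived features for {len(features)} patient-visits")
    by_visit = features.groupby("visit")[["e_mean", "f_mass"]].mean()
    for v, row in by_visit.iterrows():
        print(f"  visit {v}: mean E_mean {row['e_mean']:6.1f} kPa, "
              f"mean f_mass {row['f_mass']:6.1f} Hz")
    print(f"wrote {OUT}/features_visits.csv and change_scores.csv")


if __name__ == "__main__":
    main()
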