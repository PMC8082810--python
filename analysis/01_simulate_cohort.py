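"""Simulate the study cohort.

Generates a 62-patient synthetic cohort (34 responders / 28 non-responders)
with the published per-group, per-visit feature distributions and
missingness counts, and writes the raw visit and patient tables that the
rest of the analysis consumes.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

from swe_response.cohort import default_config, generate_cohort

SEED = 7
OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(default_config(), seed=SEED)
    cohort.visits.to_csv(OUT / "cohort_visits.csv", index=False)
    cohort.patients.to_csv(OUT / "cohort_patients.csv", index=False)
    cohort.truth.to_csv(OUT / "cohort_truth.csv", index=False)

    counts = cohort.patients.groupby("group").size()
    print(f"simulated {len(cohort.patients)} patients "
          f"({counts['responder']} responders / "
          f"{counts['nonresponder']} non-responders), seed {SEED}")
    swe_n = (
        cohort.visits.dropna(subset=["roi1_sws_mean"])
        .groupby("visit")
        .size()
    )
    for v, n in swe_n.items():
        print(f"  visit {v}: {n} patients with SWE measurements")
    print(f"wrote raw tables to {OUT}/")


if __name__ == "__main__":
    main()
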