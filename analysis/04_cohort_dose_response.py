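#!/usr/bin/env python
"""Virtual-cohort dose-response study.

Samples a seeded cohort of 200 individuals with heterogeneous drinking habits
(0-6 drinks/day, mean ~2.5, i.e. ~99 g fructose/day of the HFCS preset at the
median habit) and heterogeneous fructose absorption (30% malabsorbers at 8 h
completion), simulates each to steady state, and tabulates outcomes by
fructose intake.  Writes results/cohort_individuals.csv and
results/cohort_dose_response.csv.

Findings: the flagged-hypertensive fraction rises monotonically across
drinks/day bins, and malabsorbers carry higher aldosterone exposure than
normal absorbers at the same habit.  The table is qualitative dose-response
only: no survey covariates (age, BMI, salt habits) are emulated.
"""

from pathlib import Path

from osmotrap import CohortSpec, dose_response_table, run_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = CohortSpec(n=200, seed=20261001, sim_days=14.0)
    result = run_cohort(spec)
    result.table.to_csv(OUT / "cohort_individuals.csv", index=False)

    table = dose_response_table(result)
    table.to_csv(OUT / "cohort_dose_response.csv", index=False)
    print(table.to_string(index=False))

    df = result.table
    by_status = df[df.drinks_per_day > 0].groupby("malabsorber")[
        "mean_daily_aldo_exposure"
    ].mean()
    print(
        f"\nMean daily aldosterone exposure among drinkers: "
        f"normal {by_status.get(False, float('nan')):.3f}, "
        f"malabsorber {by_status.get(True, float('nan')):.3f}"
    )
    print(f"Overall flagged hypertensive: {df.hypertensive.mean():.1%} of n={len(df)}")


if __name__ == "__main__":
    main()
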