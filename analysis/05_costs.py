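#!/usr/bin/env python
"""Cost the projected community home-based care demand, two ways.

Project-cost method: decimal-exact aggregation of the packaged per-item
annual cost table (grand totals per year) and cross-strata state sums.
Man-hour method: bottom-up costing of the stage-04 population projection
with state-specific weekly hours, the 1.8 community coefficient and the
growth-indexed wage, split into family vs professional caregiver demand.
Writes results/cost_project_method.csv and results/cost_manhour.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fdcare.costs import (
    CareHoursMap,
    WageSchedule,
    caregiver_ratio,
    hourly_wage,
    manhour_totals,
)
from fdcare.fixtures import aggregate, load_fixture

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--family-share", type=float, default=0.7416)
    args = ap.parse_args()

    ws = WageSchedule()
    print("hourly wage (yuan):",
          {y: round(hourly_wage(ws, y), 2) for y in (2020, 2025, 2030, 2035)})

    # project-cost method from the packaged item table
    t9 = load_fixture("T9")
    years = (2020, 2025, 2030, 2035)
    grand = {y: aggregate(t9, where={"year": y}) for y in years}
    print("\nproject-cost grand totals (billion RMB):", grand)
    t8 = load_fixture("T8")
    by_state = aggregate(t8, group_by=["year", "state"])
    by_state.rename("billion").reset_index().to_csv(
        RESULTS / "cost_project_method.csv", index=False)
    print("project-cost by state (billion RMB):")
    print(by_state.unstack().to_string())

    # man-hour method on the projected population
    pop = pd.read_csv(RESULTS / "population_projection.csv")
    hm = CareHoursMap(family_share=args.family_share)
    table = manhour_totals(pop, hm, ws)
    table.round(3).to_csv(RESULTS / "cost_manhour.csv", index=False)
    by_year = table.groupby("period")[["family", "professional", "combined"]].sum()
    print("\nman-hour totals (billion RMB):")
    print(by_year.round(3).to_string())
    _, summary = caregiver_ratio(table)
    print(f"family/professional cost ratio: {summary['median']:.2f} "
          f"(min {summary['min']:.2f}, max {summary['max']:.2f})")


if __name__ == "__main__":
    main()
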