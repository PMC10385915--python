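"""The two costing methods for community home-based eldercare.

Project-cost method (item level)::

    A  materials      = (A1 disposable + A2 unit price / recyclable uses) * n ops
    B  manpower       = B1 care hours per op * B2 yuan/hour * n ops
    C  transportation = (travel hours * B2 + fare + depreciation) * n ops
    D  management     = 5% of (A + B + C)
    E  education      = 5% of (A + B + C + D)
    total             = A + B + C + D + E  =  1.1025 * (A + B + C)

Man-hour costing method (per person)::

    monthly cost = weekly care hours(state) * 4 weeks
                   * 1.80 community-care cost coefficient
                   * hourly wage(year)

Weekly hours by FC state: 10.58 (state 1), 1.5 (state 2), 7.42 (state 3),
4.5 (state 5); states 4 (healthy) and 6 (dead) consume no care.  The wage
is anchored at the 2020 urban non-private average of 97,379 yuan/year over
251 working days of 8 h (48.50 yuan/h) and compounded by period-specific
annual growth rates: 6.5% (2010-2020), 5.4% (2020-2030), 4.5% (2030-2040).
Totals split into family vs professional caregiver shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import CARE_STATES

MANAGEMENT_RATE = 0.05
EDUCATION_RATE = 0.05
WEEKS_PER_MONTH = 4
COMMUNITY_COST_COEFFICIENT = 1.80


@dataclass
class CostItem:
    """One service item of the project-cost method (all money in yuan)."""

    name: str
    category: str = ""
    A1_disposable: float = 0.0
    A2_unit_price: float = 0.0
    A2_recyclable_uses: float = 1.0
    B1_care_hours: float = 0.0
    B2_hourly_cost: float = 0.0
    C_travel_time: float = 0.0
    C_fare: float = 0.0
    C_depreciation: float = 0.0

    def __post_init__(self):
        for f in ("A1_disposable", "A2_unit_price", "B1_care_hours",
                  "B2_hourly_cost", "C_travel_time", "C_fare", "C_depreciation"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.A2_recyclable_uses < 1:
            raise ValueError("A2_recyclable_uses must be >= 1")


def project_cost_item(item: CostItem, n_operations: float) -> dict:
    """A-E decomposition and total for ``n_operations`` of one item (yuan)."""
    if n_operations < 0:
        raise ValueError("n_operations must be >= 0")
    A = (item.A1_disposable + item.A2_unit_price / item.A2_recyclable_uses) * n_operations
    B = item.B1_care_hours * item.B2_hourly_cost * n_operations
    C = (item.C_travel_time * item.B2_hourly_cost + item.C_fare
         + item.C_depreciation) * n_operations
    D = MANAGEMENT_RATE * (A + B + C)
    E = EDUCATION_RATE * (A + B + C + D)
    return dict(A=A, B=B, C=C, D=D, E=E, total=A + B + C + D + E)


def aggregate_project_costs(item_table: pd.DataFrame, years=None) -> pd.Series:
    """Grand total per year of an item-level annual cost table (billion RMB).

    ``item_table`` is tidy with columns (item, year, billion); summary rows
    (category == "Total"), if present, are excluded from the sum.
    """
    t = item_table
    if "category" in t.columns:
        t = t[t["category"] != "Total"]
    if years is not None:
        missing = set(years) - set(t["year"].unique())
        if missing:
            raise ValueError(f"missing years {sorted(missing)} in item table")
        t = t[t["year"].isin(list(years))]
    if t.empty:
        return pd.Series(dtype=float, name="billion")
    out = t.groupby("year")["billion"].sum().round(3)
    out.name = "billion"
    return out


@dataclass
class WageSchedule:
    """Growth-indexed hourly wage, anchored at the 2020 annual average."""

    base_annual_wage: float = 97_379.0
    working_days: int = 251
    hours_per_day: int = 8
    base_year: int = 2020
    growth: dict = field(default_factory=lambda: {
        (2010, 2020): 0.065,
        (2020, 2030): 0.054,
        (2030, 2040): 0.045,
    })

    def __post_init__(self):
        if any(r < 0 for r in self.growth.values()):
            raise ValueError("growth rates must be >= 0")

    @property
    def base_hourly_wage(self) -> float:
        return self.base_annual_wage / (self.working_days * self.hours_per_day)

    def _rate(self, year: int) -> float:
        for (a, b), r in self.growth.items():
            if a < year <= b:  # rate governing the step from year-1 to year
                return r
        raise ValueError(f"year {year} outside the wage schedule")

    def hourly_wage(self, year: int) -> float:
        """Hourly wage (yuan) in ``year``, compounded annually from 2020."""
        lo = min(a for a, _ in self.growth)
        hi = max(b for _, b in self.growth)
        if not lo <= year <= hi:
            raise ValueError(f"year {year} outside the wage schedule ({lo}-{hi})")
        w = self.base_hourly_wage
        if year > self.base_year:
            for y in range(self.base_year + 1, year + 1):
                w *= 1.0 + self._rate(y)
        else:
            for y in range(self.base_year, year, -1):
                w /= 1.0 + self._rate(y)
        return w


def hourly_wage(schedule: WageSchedule, year: int) -> float:
    return schedule.hourly_wage(year)


@dataclass
class CareHoursMap:
    """Weekly care hours per FC state and the family/professional split."""

    weekly_hours: dict = field(default_factory=lambda: {1: 10.58, 2: 1.5, 3: 7.42, 5: 4.5})
    community_cost_coefficient: float = COMMUNITY_COST_COEFFICIENT
    family_share: float = 0.7416

    def __post_init__(self):
        if any(h < 0 for h in self.weekly_hours.values()):
            raise ValueError("weekly hours must be >= 0")
        if self.community_cost_coefficient <= 0:
            raise ValueError("community_cost_coefficient must be > 0")
        if not 0.0 <= self.family_share <= 1.0:
            raise ValueError("family_share must lie in [0, 1]")


def manhour_monthly_cost(
    hours_map: CareHoursMap, state: int, year: int, schedule: WageSchedule
) -> float:
    """Monthly per-person community home-based care cost (yuan)."""
    if state not in hours_map.weekly_hours:
        raise ValueError(f"no care cost defined for state {state}")
    return (
        hours_map.weekly_hours[state]
        * WEEKS_PER_MONTH
        * hours_map.community_cost_coefficient
        * schedule.hourly_wage(year)
    )


def manhour_totals(
    populations: pd.DataFrame,
    hours_map: CareHoursMap | None = None,
    schedule: WageSchedule | None = None,
    years=None,
) -> pd.DataFrame:
    """Annual care cost (billion RMB) per period x stratum x state.

    ``populations`` is tidy (period, sex, age_band, state, millions); only
    the care states 1, 2, 3, 5 are costed, and all must be present.
    Returns a tidy frame with family / professional / combined columns
    (combined = family + professional exactly).
    """
    hours_map = hours_map or CareHoursMap()
    schedule = schedule or WageSchedule()
    pop = populations[populations["state"].isin(CARE_STATES)].copy()
    missing = set(CARE_STATES) - set(pop["state"].unique())
    if missing:
        raise ValueError(f"care states {sorted(missing)} missing from populations")
    if years is not None:
        pop = pop[pop["period"].isin(list(years))]
    monthly = pop.apply(
        lambda r: manhour_monthly_cost(hours_map, int(r["state"]), int(r["period"]), schedule),
        axis=1,
    )
    # yuan/month * 12 * millions of people -> billion RMB per year
    pop["combined"] = monthly * 12.0 * pop["millions"] * 1e-3
    pop["family"] = hours_map.family_share * pop["combined"]
    pop["professional"] = pop["combined"] - pop["family"]
    return pop[["period", "sex", "age_band", "state",
                "millions", "family", "professional", "combined"]]


def caregiver_ratio(cost_table: pd.DataFrame) -> tuple:
    """Family/professional cost ratio per row plus (min, median, max).

    Rows with zero professional cost get NaN and are flagged in the
    returned summary.
    """
    if not {"family", "professional"} <= set(cost_table.columns):
        raise ValueError("cost table must carry family and professional columns")
    out = cost_table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = np.where(
            out["professional"] > 0, out["family"] / out["professional"], np.nan
        )
    r = out["ratio"].dropna()
    summary = dict(
        min=float(r.min()) if len(r) else np.nan,
        median=float(r.median()) if len(r) else np.nan,
        max=float(r.max()) if len(r) else np.nan,
        undefined=int(out["ratio"].isna().sum()),
    )
    return out, summary
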