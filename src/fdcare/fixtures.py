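"""Packaged transcriptions of the printed result tables, and exact sums.

Tables T5-T11 ship as CSV transcriptions of the published tables, carried
digit-for-digit: transition matrices (T5 one-year, T6 five-year), the
population projection (T7, millions), project-method costs by stratum (T8)
and by service item (T9), and man-hour-method caregiver costs (T10 family,
T11 professional), all in billion RMB.  Printed anomalies (rows that do
not sum to one, repeated columns) are flagged, never altered.

Aggregation is decimal-exact: cells are accumulated as scaled integers via
``decimal.Decimal`` so that 3-decimal printed values sum without binary
floating-point drift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .states import N_STATES

_FILES = {
    "T5": "table5_transition_1y.csv",
    "T6": "table6_transition_5y.csv",
    "T7": "table7_population.csv",
    "T8": "table8_project_cost_by_stratum.csv",
    "T9": "table9_project_cost_by_item.csv",
    "T10": "table10_family_care_cost.csv",
    "T11": "table11_professional_care_cost.csv",
}

#: row-sum tolerance for flagging transition-matrix fixture rows
ROW_SUM_TOL = 0.005

_YEARS = ("y2020", "y2025", "y2030", "y2035")


@dataclass
class FixtureTable:
    table_id: str
    data: pd.DataFrame  # tidy rows, with value columns as str for exactness
    flags: pd.DataFrame  # per-row validity notes (empty when clean)

    @property
    def values(self) -> pd.DataFrame:
        """Tidy frame with the value column as float."""
        out = self.data.copy()
        out[self.value_column] = out[self.value_column].astype(float)
        return out

    @property
    def value_column(self) -> str:
        return "prob" if self.table_id in ("T5", "T6") else (
            "millions" if self.table_id == "T7" else "billion"
        )


def _read_raw(table_id: str) -> pd.DataFrame:
    try:
        fname = _FILES[table_id]
    except KeyError:
        raise KeyError(f"unknown fixture table {table_id!r}") from None
    with resources.files("fdcare.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, dtype=str)


def load_fixture(table_id: str) -> FixtureTable:
    """Load a printed-table fixture in tidy form with validity flags."""
    raw = _read_raw(table_id)
    flags = []
    if table_id in ("T5", "T6"):
        long = raw.melt(
            id_vars=["sex", "age_band", "from_state"],
            value_vars=[f"p{i}" for i in range(1, N_STATES + 1)],
            var_name="to_state", value_name="prob",
        )
        long["to_state"] = long["to_state"].str[1:].astype(int)
        long["from_state"] = long["from_state"].astype(int)
        for _, row in raw.iterrows():
            s = sum(Decimal(row[f"p{i}"]) for i in range(1, N_STATES + 1))
            if abs(s - 1) > Decimal(str(ROW_SUM_TOL)):
                flags.append(dict(sex=row["sex"], age_band=row["age_band"],
                                  from_state=int(row["from_state"]),
                                  note=f"row sums to {s}, not 1"))
        data = long
    elif table_id == "T9":
        data = raw.melt(id_vars=["category", "item"], value_vars=list(_YEARS),
                        var_name="year", value_name="billion")
        data["year"] = data["year"].str[1:].astype(int)
        items = raw[raw["category"] != "Total"]
        totals = raw[raw["category"] == "Total"]
        for y in _YEARS:
            s = sum(Decimal(v) for v in items[y])
            printed = Decimal(totals[y].iloc[0])
            if s != printed:
                flags.append(dict(item="Above all projects", year=int(y[1:]),
                                  note=f"printed total {printed} != item sum {s}"))
    else:
        value = "millions" if table_id == "T7" else "billion"
        data = raw.melt(id_vars=["sex", "age_band", "state"], value_vars=list(_YEARS),
                        var_name="year", value_name=value)
        data["year"] = data["year"].str[1:].astype(int)
        data["state"] = data["state"].astype(int)
        if table_id in ("T10", "T11"):
            dup = raw[raw["y2030"] == raw["y2035"]]
            for _, row in dup.iterrows():
                flags.append(dict(sex=row["sex"], age_band=row["age_band"],
                                  state=int(row["state"]),
                                  note="2030 and 2035 columns repeat in the printed source"))
    return FixtureTable(table_id, data, pd.DataFrame(flags))


def aggregate(table, value_column: str | None = None, group_by=None, where=None):
    """Decimal-exact sum of selected cells, reported to 3 decimals.

    ``table`` is a FixtureTable or any tidy DataFrame whose value column
    holds printed decimal strings or floats.  ``where`` is a dict of
    column -> scalar or list filters.  With ``group_by`` a Series of group
    sums is returned, otherwise a single float.  An empty selection warns
    and returns 0.
    """
    if isinstance(table, FixtureTable):
        df = table.data
        value_column = value_column or table.value_column
        if table.table_id == "T9":
            df = df[df["category"] != "Total"]
    else:
        df = table
        if value_column is None:
            raise ValueError("value_column required for a plain DataFrame")
    for col, sel in (where or {}).items():
        if col not in df.columns:
            raise KeyError(f"no column {col!r} to filter on")
        sel = sel if isinstance(sel, (list, tuple, set)) else [sel]
        df = df[df[col].isin(list(sel))]
    if df.empty:
        import warnings
        warnings.warn("empty selection; aggregate is 0", stacklevel=2)
        return 0.0

    def dsum(series):
        return float(round(sum(Decimal(str(v)) for v in series), 3))

    if group_by:
        for col in group_by if isinstance(group_by, (list, tuple)) else [group_by]:
            if col not in df.columns:
                raise KeyError(f"no column {col!r} to group on")
        return df.groupby(group_by)[value_column].apply(dsum)
    return dsum(df[value_column])


def fixture_transition_matrix(table_id: str, sex: str, age_band: str) -> np.ndarray:
    """6x6 probability matrix for one stratum from a T5/T6 fixture."""
    t = load_fixture(table_id)
    sub = t.values
    sub = sub[(sub["sex"] == sex) & (sub["age_band"] == age_band)]
    P = np.zeros((N_STATES, N_STATES))
    for _, r in sub.iterrows():
        P[int(r["from_state"]) - 1, int(r["to_state"]) - 1] = r["prob"]
    return P


def write_tidy(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_tidy(path) -> pd.DataFrame:
    return pd.read_csv(path)


def run_manifest(path, *, config: dict, seed, inputs: dict | None = None) -> dict:
    """Write a reproducibility manifest: config hash, seed, input checksums."""
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {},
    }
    for name, p in (inputs or {}).items():
        with open(p, "rb") as fh:
            manifest["inputs"][name] = hashlib.sha256(fh.read()).hexdigest()
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
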