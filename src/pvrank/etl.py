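"""Cohort selection, event cleaning, and episode assembly.

Cleaning implements the four raw-data error classes — missing identifiers,
missing values, outliers, and measurement-unit errors — as explicit,
configurable rules.  Every operation returns a per-reason tally so that
input rows = retained rows + sum of rejections (conservation) can be
asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import canonical_units, default_range_table

__all__ = [
    "StayRecord",
    "EpisodeTimeSeries",
    "CleanReport",
    "select_cohort",
    "clean_events",
    "build_episodes",
    "read_events",
    "read_stays",
    "read_labels",
]

EVENT_COLUMNS = ["stay_id", "patient_id", "variable", "time_h", "value", "unit"]
STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "admission_id",
    "age_years",
    "duration_h",
    "stays_in_admission",
    "transferred",
]

#: unit aliases convertible to the canonical unit, per PV: alias -> (scale, offset)
UNIT_CONVERSIONS: dict[str, dict[str, tuple[float, float]]] = {
    "TEMP": {"F": (5.0 / 9.0, -32.0 * 5.0 / 9.0), "f": (5.0 / 9.0, -32.0 * 5.0 / 9.0)},
    "Weight": {"lb": (0.45359237, 0.0), "lbs": (0.45359237, 0.0)},
    "Ht": {"in": (2.54, 0.0), "inch": (2.54, 0.0)},
}


@dataclass(frozen=True)
class StayRecord:
    stay_id: str
    patient_id: str
    admission_id: str
    age_years: float
    duration_h: float
    stays_in_admission: int
    transferred: bool


@dataclass
class EpisodeTimeSeries:
    """Per-stay, per-PV sorted measurement sequences over the stay."""

    stay_id: str
    duration_h: float
    series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def get(self, pv: str) -> tuple[np.ndarray, np.ndarray]:
        if pv in self.series:
            return self.series[pv]
        empty = np.empty(0)
        return empty, empty


@dataclass
class CleanReport:
    """Accounting of one cleaning/selection pass."""

    n_input: int
    n_retained: int
    rejections: dict[str, int]
    removed_index: pd.Index
    n_converted: int = 0

    def conserved(self) -> bool:
        return self.n_input == self.n_retained + sum(self.rejections.values())


def select_cohort(
    stays: pd.DataFrame, min_age: float = 16.0
) -> tuple[set[str], CleanReport]:
    """Apply the cohort rules: adults only, single non-transferred ICU stays.

    Returns the retained stay-id set and a per-rule exclusion tally.  Rows
    with missing required fields are rejected as ``malformed``.
    """
    if stays.empty:
        raise ValueError("stays table is empty")
    missing_cols = [c for c in STAY_COLUMNS if c not in stays.columns]
    if missing_cols:
        raise ValueError(f"stays table missing columns: {missing_cols}")

    required = stays[["stay_id", "age_years", "duration_h", "stays_in_admission", "transferred"]]
    malformed = required.isna().any(axis=1) | (stays["stay_id"].astype(str).str.strip() == "")
    ok = ~malformed
    underage = ok & (stays["age_years"] < min_age)
    ok &= ~underage
    multi = ok & (stays["stays_in_admission"].astype(float) != 1)
    ok &= ~multi
    transferred = ok & (stays["transferred"].astype(float) != 0)
    ok &= ~transferred

    report = CleanReport(
        n_input=len(stays),
        n_retained=int(ok.sum()),
        rejections={
            "malformed": int(malformed.sum()),
            "underage": int(underage.sum()),
            "multiple_stays": int(multi.sum()),
            "transferred": int(transferred.sum()),
        },
        removed_index=stays.index[~ok],
    )
    return set(stays.loc[ok, "stay_id"].astype(str)), report


def clean_events(
    events: pd.DataFrame,
    range_table: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, CleanReport]:
    """Drop invalid events and canonicalize units.

    Rejection rules, applied in order (each row counted once, under the
    first rule it trips): blank stay id, unknown variable name, missing
    value, negative timestamp, out-of-plausible-range value *after* unit
    conversion.  Convertible units (°F→°C, lb→kg, in→cm) are converted in
    place and the unit field set to the canonical unit.
    """
    if range_table is None:
        range_table = default_range_table()
    missing_cols = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing_cols:
        raise ValueError(f"events table missing columns: {missing_cols}")

    df = events.copy()
    units = canonical_units()

    blank = df["stay_id"].isna() | (df["stay_id"].astype(str).str.strip() == "")
    known = df["variable"].isin(range_table.keys())
    unknown = ~blank & ~known
    missing_value = ~blank & known & df["value"].isna()
    negative_time = ~blank & known & ~missing_value & (df["time_h"] < 0)
    candidate = ~(blank | unknown | missing_value | negative_time)

    # unit conversion on candidate rows
    value = df["value"].to_numpy(dtype=float, copy=True)
    unit = df["unit"].astype(str).fillna("").to_numpy(dtype=object)
    n_converted = 0
    for pv, aliases in UNIT_CONVERSIONS.items():
        for alias, (scale, offset) in aliases.items():
            sel = (candidate & (df["variable"] == pv) & (pd.Series(unit, index=df.index) == alias)).to_numpy()
            if sel.any():
                value[sel] = value[sel] * scale + offset
                unit[sel] = units.get(pv, "")
                n_converted += int(sel.sum())
    df["value"] = np.round(value, 10)
    df["unit"] = unit

    lo = df["variable"].map({pv: r[0] for pv, r in range_table.items()})
    hi = df["variable"].map({pv: r[1] for pv, r in range_table.items()})
    out_of_range = candidate & ((df["value"] < lo) | (df["value"] > hi))
    keep = candidate & ~out_of_range

    # canonical units on retained rows (blank/unrecognized units treated as canonical)
    retained = df.loc[keep].copy()
    retained["unit"] = retained["variable"].map(units).fillna("")

    report = CleanReport(
        n_input=len(df),
        n_retained=int(keep.sum()),
        rejections={
            "blank_stay_id": int(blank.sum()),
            "unknown_variable": int(unknown.sum()),
            "missing_value": int(missing_value.sum()),
            "negative_time": int(negative_time.sum()),
            "out_of_range": int(out_of_range.sum()),
        },
        removed_index=df.index[~keep],
        n_converted=n_converted,
    )
    return retained, report


def build_episodes(
    events: pd.DataFrame, stays: pd.DataFrame, retained_ids: set[str] | None = None
) -> tuple[list[EpisodeTimeSeries], dict[str, int]]:
    """Assemble per-stay, per-PV sorted time series from cleaned events.

    Events are sorted by time within each (stay, PV); duplicate timestamps
    collapse to their mean value; events after the recorded stay duration
    or for stays outside the retained set are dropped and counted.
    """
    if retained_ids is None:
        retained_ids = set(stays["stay_id"].astype(str))
    stays_idx = stays.set_index("stay_id")
    durations = stays_idx["duration_h"].to_dict()

    tally = {"unknown_stay": 0, "after_discharge": 0, "deduplicated": 0}
    in_cohort = events["stay_id"].isin(retained_ids)
    tally["unknown_stay"] = int((~in_cohort).sum())
    ev = events.loc[in_cohort]

    dur = ev["stay_id"].map(durations)
    late = ev["time_h"] > dur
    tally["after_discharge"] = int(late.sum())
    ev = ev.loc[~late]

    # collapse duplicate timestamps to the mean value
    grouped = (
        ev.groupby(["stay_id", "variable", "time_h"], sort=True)["value"].mean().reset_index()
    )
    tally["deduplicated"] = len(ev) - len(grouped)

    episodes: dict[str, EpisodeTimeSeries] = {
        str(sid): EpisodeTimeSeries(stay_id=str(sid), duration_h=float(durations[sid]))
        for sid in sorted(retained_ids)
        if sid in durations
    }
    # split into per-(stay, PV) slices without per-group DataFrame creation
    sids = grouped["stay_id"].to_numpy(dtype=object)
    pvs = grouped["variable"].to_numpy(dtype=object)
    times = grouped["time_h"].to_numpy(dtype=float)
    values = grouped["value"].to_numpy(dtype=float)
    if len(grouped):
        change = np.flatnonzero((sids[1:] != sids[:-1]) | (pvs[1:] != pvs[:-1]))
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(grouped)]])
        for a, b in zip(starts, ends):
            episodes[str(sids[a])].series[pvs[a]] = (times[a:b].copy(), values[a:b].copy())
    return list(episodes.values()), tally


# ---------------------------------------------------------------------------
# table readers (delimited text, header row, UTF-8)


def _read_csv_checked(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stay_id": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header in {path}: missing columns {missing}")
    return df


def read_events(path) -> pd.DataFrame:
    df = _read_csv_checked(path, EVENT_COLUMNS)
    df["stay_id"] = df["stay_id"].fillna("")
    return df


def read_stays(path) -> pd.DataFrame:
    return _read_csv_checked(path, STAY_COLUMNS)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stay_id": str})
    if "stay_id" not in df.columns:
        raise ValueError(f"malformed header in {path}: missing stay_id")
    return df
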