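"""CSV schemas and round-trip helpers.

All files are UTF-8, comma-delimited with a header row; months are
serialised as YYYY-MM, dates as ISO-8601.  Three input tables drive the
analysis:

* areas:    area_id, lat, lon, imd_score, total_pop, ethnic_density,
            pop_density, urban_flag
* events:   event_id, lat, lon, launch_date, closure_date (may be empty)
* finishers (long): area_id, month, count

The derived distance panel is written as
area_id, month, distance_km, nearest_event_id.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

AREA_COLUMNS = [
    "area_id",
    "lat",
    "lon",
    "imd_score",
    "total_pop",
    "ethnic_density",
    "pop_density",
    "urban_flag",
]
EVENT_COLUMNS = ["event_id", "lat", "lon", "launch_date", "closure_date"]
FINISHER_COLUMNS = ["area_id", "month", "count"]
DISTANCE_COLUMNS = ["area_id", "month", "distance_km", "nearest_event_id"]


def write_areas(areas: pd.DataFrame, path) -> None:
    areas.to_csv(path, index=False, columns=AREA_COLUMNS)


def read_areas(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    df["urban_flag"] = df["urban_flag"].astype(bool)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    for col in ("launch_date", "closure_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"event_id": str})
    df["launch_date"] = pd.to_datetime(df["launch_date"])
    df["closure_date"] = pd.to_datetime(df.get("closure_date"))
    return df


def write_finishers(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=FINISHER_COLUMNS)


def read_finishers(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"area_id": str, "month": str})


def write_distance_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=DISTANCE_COLUMNS)


def read_distance_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"area_id": str, "month": str, "nearest_event_id": str})


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
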