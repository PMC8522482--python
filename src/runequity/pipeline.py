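"""End-to-end pipeline: inputs -> distances -> descriptives -> RII ->
yearly determinant models, with input validation and a reproducibility
manifest.

A :class:`PipelineConfig` either points at the three input CSVs or carries
a synthetic block; a rerun with the same configuration produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import runequity
from runequity import io
from runequity.descriptives import panel_summary, quintile_series
from runequity.geo import build_distance_panel
from runequity.inequality import rii_series
from runequity.participation import fit_yearly_determinants
from runequity.synthetic import GenerativeTruth, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    areas_csv: str | None = None
    events_csv: str | None = None
    finishers_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    start_month: str = "2010-01"
    end_month: str = "2019-12"
    family: str = "poisson"
    stratum: str = "all"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_paths = all(
            p is not None for p in (self.areas_csv, self.events_csv, self.finishers_csv)
        )
        if not have_paths and self.synthetic is None:
            raise ValueError("config needs either the three input CSVs or a synthetic block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        if syn is not None:
            truth = GenerativeTruth(**syn.pop("truth", {}))
            syn = SyntheticConfig(truth=truth, **syn)
        return cls(synthetic=syn, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(areas_csv, events_csv, finishers_csv) -> list[dict]:
    """Schema / range / referential-integrity checks on the input CSVs.

    Returns a list of violation dicts (file, row, column, message); empty
    means the inputs are valid.  Row numbers are 0-based data rows.
    """
    violations: list[dict] = []

    def flag(file, row, column, message):
        violations.append({"file": str(file), "row": row, "column": column, "message": message})

    try:
        areas = io.read_areas(areas_csv)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        flag(areas_csv, None, None, f"unreadable: {exc}")
        areas = None
    if areas is not None:
        missing = set(io.AREA_COLUMNS) - set(areas.columns)
        if missing:
            flag(areas_csv, None, None, f"missing columns: {sorted(missing)}")
        else:
            checks = [
                ("imd_score", lambda s: (s > 0) & (s <= 100), "imd_score outside (0, 100]"),
                ("ethnic_density", lambda s: (s >= 0) & (s <= 100), "ethnic_density outside [0, 100]"),
                ("total_pop", lambda s: s >= 1, "total_pop below 1"),
                ("pop_density", lambda s: s > 0, "pop_density not positive"),
                ("lat", lambda s: (s >= -90) & (s <= 90), "latitude outside [-90, 90]"),
                ("lon", lambda s: (s >= -180) & (s <= 180), "longitude outside [-180, 180]"),
            ]
            for col, ok, msg in checks:
                bad = areas.index[~ok(areas[col])]
                for row in bad:
                    flag(areas_csv, int(row), col, msg)
            dup = areas.index[areas["area_id"].duplicated()]
            for row in dup:
                flag(areas_csv, int(row), "area_id", "duplicate area_id")

    try:
        events = io.read_events(events_csv)
    except Exception as exc:  # noqa: BLE001
        flag(events_csv, None, None, f"unreadable: {exc}")
        events = None
    if events is not None:
        if events["launch_date"].isna().any():
            for row in events.index[events["launch_date"].isna()]:
                flag(events_csv, int(row), "launch_date", "unparseable launch date")
        bad = events.index[
            events["closure_date"].notna() & (events["closure_date"] <= events["launch_date"])
        ]
        for row in bad:
            flag(events_csv, int(row), "closure_date", "closure not after launch")

    try:
        fin = io.read_finishers(finishers_csv)
    except Exception as exc:  # noqa: BLE001
        flag(finishers_csv, None, None, f"unreadable: {exc}")
        fin = None
    if fin is not None:
        bad = fin.index[(fin["count"] < 0) | (fin["count"] != fin["count"].astype(int))]
        for row in bad:
            flag(finishers_csv, int(row), "count", "count not a nonnegative integer")
        bad_month = fin.index[~fin["month"].str.fullmatch(r"\d{4}-\d{2}")]
        for row in bad_month:
            flag(finishers_csv, int(row), "month", "month not YYYY-MM")
        if areas is not None and "area_id" in areas.columns:
            known = set(areas["area_id"])
            orphan = fin.index[~fin["area_id"].isin(known)]
            for row in orphan:
                flag(
                    finishers_csv,
                    int(row),
                    "area_id",
                    "area_id not present in areas table",
                )
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write artifacts under ``config.out_dir``.

    Produces areas/events/finisher CSVs (when synthesising), the distance
    panel, monthly and yearly quintile tables, a covariate summary, both
    RII series, the yearly coefficient table, and ``manifest.json`` with
    input hashes, the seed and the package version.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.synthetic.seed + config.seed)
        data = generate_dataset(syn)
        areas, events = data["areas"], data["events"]
        finishers = data["finisher_panel"]
        distance_panel = data["distance_panel"]
        start, end = syn.start_month, syn.end_month
        io.write_areas(areas, out / "areas.csv")
        io.write_events(events, out / "events.csv")
        io.write_finishers(finishers, out / "finishers.csv")
        input_files = [out / "areas.csv", out / "events.csv", out / "finishers.csv"]
    else:
        report = validate_inputs(config.areas_csv, config.events_csv, config.finishers_csv)
        if report:
            first = report[0]
            raise ValueError(
                f"input validation failed ({len(report)} violations); first: "
                f"{first['file']} row {first['row']} column {first['column']}: {first['message']}"
            )
        areas = io.read_areas(config.areas_csv)
        events = io.read_events(config.events_csv)
        finishers = io.read_finishers(config.finishers_csv)
        start, end = config.start_month, config.end_month
        distance_panel = build_distance_panel(areas, events, (start, end))
        input_files = [Path(config.areas_csv), Path(config.events_csv), Path(config.finishers_csv)]

    io.write_distance_panel(distance_panel, out / "distance_panel.csv")

    q_month = quintile_series(areas, distance_panel, finishers, by="month")
    q_year = quintile_series(areas, distance_panel, finishers, by="year")
    io.write_csv(q_month, out / "quintile_month.csv")
    io.write_csv(q_year, out / "quintile_year.csv")
    io.write_csv(panel_summary(areas), out / "panel_summary.csv")

    months = (start, end)
    rii_d = rii_series(areas, distance_panel, months, "distance")
    rii_p = rii_series(areas, finishers, months, "participation")
    io.write_csv(rii_d, out / "rii_distance.csv")
    io.write_csv(rii_p, out / "rii_participation.csv")

    years = sorted({int(m[:4]) for m in distance_panel["month"].unique()})
    coefs = fit_yearly_determinants(
        areas, finishers, distance_panel, years, family=config.family, stratum=config.stratum
    )
    io.write_csv(coefs, out / "determinants.csv")

    artifacts = [
        "distance_panel.csv",
        "quintile_month.csv",
        "quintile_year.csv",
        "panel_summary.csv",
        "rii_distance.csv",
        "rii_participation.csv",
        "determinants.csv",
    ]
    manifest = {
        "version": runequity.__version__,
        "seed": config.seed,
        "family": config.family,
        "stratum": config.stratum,
        "month_range": [start, end],
        "inputs": {p.name: _sha256(p) for p in input_files},
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
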