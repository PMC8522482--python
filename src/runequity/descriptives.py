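"""Deprivation quintiles and descriptive summary tables.

Quintile 1 is the least deprived fifth of areas, quintile 5 the most
deprived.  All rates are unweighted means of area-level rates — the analysis
is ecological, conducted at the small-area level without population
weighting.  A pooled (count-sum over population-sum) variant is available
behind a flag for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_QUINTILES = 5

AREA_COVARIATES = ["imd_score", "ethnic_density", "total_pop", "pop_density"]


def assign_quintiles(areas: pd.DataFrame) -> pd.Series:
    """Map area_id -> deprivation quintile (1 = least deprived).

    Areas are ranked by deprivation score ascending (score ties broken by
    area_id for determinism) and split into five groups as equal as
    possible, any remainder going to the lower quintiles.
    """
    n = len(areas)
    if n < N_QUINTILES:
        raise ValueError(f"need at least {N_QUINTILES} areas, got {n}")
    order = areas[["area_id", "imd_score"]].sort_values(["imd_score", "area_id"])
    base, rem = divmod(n, N_QUINTILES)
    sizes = [base + 1 if q < rem else base for q in range(N_QUINTILES)]
    labels = np.repeat(np.arange(1, N_QUINTILES + 1), sizes)
    return pd.Series(labels, index=order["area_id"].to_numpy(), name="quintile")


def quintile_series(
    areas: pd.DataFrame,
    distance_panel: pd.DataFrame,
    finisher_panel: pd.DataFrame,
    by: str = "month",
    *,
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean distance and finishers per 1000 persons per period and quintile.

    Parameters
    ----------
    by : "month" (period = YYYY-MM) or "year".  Yearly rates use the year's
        summed counts; the yearly distance is the mean of the area's monthly
        distances.
    pooled : if True, rates are 1000 * (summed counts) / (summed population)
        instead of the default unweighted mean of area-level rates.

    Returns (period, quintile, mean_distance_km, finishers_per_1000) with
    quintile levels "1".."5" and "overall".
    """
    if by not in ("month", "year"):
        raise ValueError("by must be 'month' or 'year'")
    quint = assign_quintiles(areas).rename_axis("area_id").reset_index()

    df = distance_panel.merge(
        finisher_panel, on=["area_id", "month"], validate="one_to_one"
    )
    missing = set(df["area_id"]) - set(areas["area_id"])
    if missing:
        raise ValueError(f"panel areas missing from areas table: {sorted(missing)[:5]}")
    df = df.merge(areas[["area_id", "total_pop"]], on="area_id").merge(quint, on="area_id")

    if by == "year":
        df["period"] = df["month"].str.slice(0, 4)
        df = (
            df.groupby(["area_id", "period", "quintile", "total_pop"], as_index=False)
            .agg(distance_km=("distance_km", "mean"), count=("count", "sum"))
        )
    else:
        df = df.rename(columns={"month": "period"})

    def _summary(g: pd.DataFrame) -> pd.Series:
        if pooled:
            rate = 1000.0 * g["count"].sum() / g["total_pop"].sum()
        else:
            rate = float((1000.0 * g["count"] / g["total_pop"]).mean())
        return pd.Series(
            {"mean_distance_km": g["distance_km"].mean(), "finishers_per_1000": rate}
        )

    per_q = (
        df.groupby(["period", "quintile"])[["distance_km", "count", "total_pop"]]
        .apply(_summary)
        .reset_index()
    )
    per_q["quintile"] = per_q["quintile"].astype(str)
    overall = (
        df.groupby("period")[["distance_km", "count", "total_pop"]]
        .apply(_summary)
        .reset_index()
    )
    overall["quintile"] = "overall"
    out = pd.concat([per_q, overall], ignore_index=True)
    return out.sort_values(["period", "quintile"]).reset_index(drop=True)


def panel_summary(areas: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Mean/min/quartile/median/max of the time-invariant area covariates.

    Quartiles use linear interpolation between order statistics (the type-7
    convention, numpy's default).
    """
    if len(areas) == 0:
        raise ValueError("areas is empty")
    variables = variables or [v for v in AREA_COVARIATES if v in areas.columns]
    rows = []
    for v in variables:
        x = areas[v].to_numpy(float)
        rows.append(
            {
                "variable": v,
                "mean": x.mean(),
                "min": x.min(),
                "p25": np.quantile(x, 0.25),
                "median": np.quantile(x, 0.5),
                "p75": np.quantile(x, 0.75),
                "max": x.max(),
            }
        )
    return pd.DataFrame(rows)
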