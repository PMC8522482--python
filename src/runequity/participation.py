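"""Yearly multivariable determinants of participation.

For each year, finisher counts are summed over the year's months per area
and regressed (Poisson, log link, log-population offset) on deprivation
score, ethnic density, population density and distance to the nearest
event.  The distance covariate is the mean of the area's monthly distances
within the year.  Population density enters in thousands of persons per
square kilometre (``POP_DENSITY_SCALE``).

The quasi-Poisson family keeps the Poisson point estimates and inflates the
standard errors by the square root of the Pearson dispersion estimate.  The
urban/rural strata re-run the model on the corresponding subset of areas.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from runequity.inequality import fit_poisson_glm

logger = logging.getLogger(__name__)

POP_DENSITY_SCALE = 1000.0  # persons/km^2 per unit of the fitted covariate

TERMS = ["intercept", "imd_score", "ethnic_density", "pop_density_scaled", "distance_km"]

FAMILIES = ("poisson", "quasipoisson")
STRATA = ("all", "urban", "rural")


def _yearly_table(
    areas: pd.DataFrame,
    finisher_panel: pd.DataFrame,
    distance_panel: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    months = [f"{year}-{m:02d}" for m in range(1, 13)]
    fp = finisher_panel[finisher_panel["month"].isin(months)]
    dp = distance_panel[distance_panel["month"].isin(months)]
    got_f, got_d = set(fp["month"]), set(dp["month"])
    lacking = [m for m in months if m not in got_f or m not in got_d]
    if lacking:
        raise ValueError(f"panels do not cover all months of {year}: missing {lacking}")
    counts = fp.groupby("area_id", as_index=False)["count"].sum()
    dist = dp.groupby("area_id", as_index=False)["distance_km"].mean()
    df = (
        areas[["area_id", "imd_score", "ethnic_density", "pop_density", "total_pop", "urban_flag"]]
        .merge(counts, on="area_id")
        .merge(dist, on="area_id")
    )
    df["pop_density_scaled"] = df["pop_density"] / POP_DENSITY_SCALE
    return df


def fit_yearly_determinants(
    areas: pd.DataFrame,
    finisher_panel: pd.DataFrame,
    distance_panel: pd.DataFrame,
    years,
    family: str = "poisson",
    stratum: str = "all",
) -> pd.DataFrame:
    """Coefficient table of the yearly participation models.

    Returns one row per (year, term) with columns estimate, std_error,
    log_likelihood, aic, n_obs and dispersion (the Pearson estimate; under
    the plain Poisson family it is reported but unused).  A year whose
    stratum has zero finishers in total is non-estimable and is omitted
    with a logged message.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")

    rows = []
    for year in years:
        df = _yearly_table(areas, finisher_panel, distance_panel, int(year))
        if stratum == "urban":
            df = df[df["urban_flag"].astype(bool)]
        elif stratum == "rural":
            df = df[~df["urban_flag"].astype(bool)]
        if df["count"].sum() == 0:
            logger.warning("year %s, stratum %s: zero finishers, model omitted", year, stratum)
            continue
        y = df["count"].to_numpy()
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["imd_score"].to_numpy(float),
                df["ethnic_density"].to_numpy(float),
                df["pop_density_scaled"].to_numpy(float),
                df["distance_km"].to_numpy(float),
            ]
        )
        fit = fit_poisson_glm(X, y, offset=np.log(df["total_pop"].to_numpy(float)))
        mu = fit.fitted_values
        n, p = X.shape
        dispersion = float(np.sum((y - mu) ** 2 / mu) / (n - p))
        se = fit.standard_errors
        if family == "quasipoisson":
            se = se * np.sqrt(dispersion)
        for term, est, s in zip(TERMS, fit.coefficients, se):
            rows.append(
                {
                    "year": int(year),
                    "term": term,
                    "estimate": float(est),
                    "std_error": float(s),
                    "log_likelihood": fit.log_likelihood,
                    "aic": fit.aic,
                    "n_obs": n,
                    "dispersion": dispersion,
                }
            )
    return pd.DataFrame(rows)
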