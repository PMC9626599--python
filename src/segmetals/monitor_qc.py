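"""QC and annual aggregation of daily speciated PM2.5 monitor records.

Daily records (one row per monitor-date-component, CSN/IMPROVE-style "long"
layout) are filtered to valid samples, monitors are screened by annual
completeness (a monitor-component-year must report strictly more than 50% of
its expected every-third-day schedule, ~121 samples), below-detection-limit
values are kept by default (optionally imputed as MDL/sqrt(2)), and retained
monitor means are averaged, unweighted, across each county's monitors.

Units: trace metals are carried in ng/m3 and PM2.5 in ug/m3; the factor of
10^3 is applied exactly once, when a metal county mean is divided by the
PM2.5 county mean to obtain the dimensionless mass proportion.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, UnitError

logger = logging.getLogger(__name__)

#: Components and their storage units.
METAL_COMPONENTS = ("Cu", "Zn", "Ni", "Cr", "Pb", "V", "Fe", "Mn", "Ti")
COMPONENT_UNITS: Mapping[str, str] = {**{m: "ng/m3" for m in METAL_COMPONENTS},
                                      "PM25": "ug/m3"}
#: ng per ug — applied when normalising a metal by PM2.5 mass.
UG_TO_NG = 1e3

#: Expected annual sample count under the every-third-day schedule.
EXPECTED_ANNUAL_SAMPLES = 121

RECORD_COLUMNS = [
    "monitor_id", "county_id", "date", "component", "concentration",
    "mdl", "valid", "urban", "region", "latitude", "longitude",
]


def read_monitor_csv(path) -> pd.DataFrame:
    """Read a daily monitor record CSV (ISO-8601 dates, 5-char FIPS ids)."""
    df = pd.read_csv(path, dtype={"county_id": str, "monitor_id": str},
                     parse_dates=["date"])
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"monitor CSV missing columns {sorted(missing)}")
    return df


def filter_valid(records: pd.DataFrame) -> pd.DataFrame:
    """Keep rows flagged valid with a non-missing concentration, order preserved."""
    keep = records["valid"].astype(bool) & records["concentration"].notna()
    out = records.loc[keep]
    logger.info("filter_valid: kept %d of %d rows", len(out), len(records))
    return out


def impute_below_mdl(records: pd.DataFrame, strategy: str = "keep") -> pd.DataFrame:
    """Handle below-detection-limit values.

    ``keep`` returns the table unchanged (below-MDL values are retained so the
    data are not skewed toward higher concentrations).  ``mdl_over_sqrt2``
    replaces every concentration strictly below its MDL with MDL/sqrt(2), the
    standard substitution for censored concentration data; values at or above
    the MDL are untouched.
    """
    if strategy == "keep":
        return records
    if strategy != "mdl_over_sqrt2":
        raise ConfigurationError(f"unknown MDL strategy {strategy!r}")
    out = records.copy()
    below = out["concentration"] < out["mdl"]
    out.loc[below, "concentration"] = out.loc[below, "mdl"] / np.sqrt(2.0)
    logger.info("impute_below_mdl: substituted %d below-MDL rows", int(below.sum()))
    return out


def annual_monitor_mean(
    records: pd.DataFrame,
    year: int,
    min_completeness: float = 0.5,
    expected_n: int | Mapping[str, int] = EXPECTED_ANNUAL_SAMPLES,
) -> pd.DataFrame:
    """Annual mean per monitor-component, screened by completeness.

    A monitor-component-year is retained iff n_samples / expected_n is
    strictly greater than ``min_completeness`` ("greater than 50%": exactly
    half the schedule is rejected).  Retained entries carry the plain
    arithmetic mean of the daily concentrations, below-MDL values included.

    ``expected_n`` may be a single schedule length or a per-monitor mapping
    (monitors that started mid-year have shorter schedules).
    """
    sub = records.loc[records["date"].dt.year == year]
    if len(sub) == 0:
        logger.info("annual_monitor_mean: no records for year %d", year)
        return pd.DataFrame(columns=[
            "monitor_id", "county_id", "component", "year", "mean_concentration",
            "n_samples", "expected_n", "completeness", "urban", "region",
            "latitude", "longitude",
        ])
    grouped = sub.groupby(["monitor_id", "county_id", "component"], sort=True)
    agg = grouped.agg(
        mean_concentration=("concentration", "mean"),
        n_samples=("concentration", "size"),
        urban=("urban", "first"),
        region=("region", "first"),
        latitude=("latitude", "first"),
        longitude=("longitude", "first"),
    ).reset_index()
    agg["year"] = year
    if isinstance(expected_n, Mapping):
        agg["expected_n"] = agg["monitor_id"].map(expected_n).astype(int)
    else:
        agg["expected_n"] = int(expected_n)
    agg["completeness"] = agg["n_samples"] / agg["expected_n"]
    retained = agg.loc[agg["completeness"] > min_completeness].reset_index(drop=True)
    logger.info(
        "annual_monitor_mean(%d): retained %d of %d monitor-component series",
        year, len(retained), len(agg),
    )
    return retained


def county_annual_exposure(monitor_means: pd.DataFrame) -> pd.DataFrame:
    """Average retained monitor means, unweighted, within each county.

    Adds the PM2.5 mass proportion (county metal mean / county PM2.5 mean,
    after the ng-per-ug unit harmonisation); absent where the county lacks a
    retained PM2.5 value.
    """
    unknown = set(monitor_means["component"]) - set(COMPONENT_UNITS)
    if unknown:
        raise UnitError(
            f"components {sorted(unknown)} have no unit metadata; "
            "cannot harmonise for mass proportions"
        )
    grouped = monitor_means.groupby(["county_id", "component", "year"], sort=True)
    county = grouped.agg(
        mean_concentration=("mean_concentration", "mean"),
        n_monitors=("monitor_id", "nunique"),
        n_samples=("n_samples", "sum"),
        completeness=("completeness", "min"),
        urban=("urban", "max"),
        region=("region", "first"),
        latitude=("latitude", "mean"),
        longitude=("longitude", "mean"),
    ).reset_index()

    pm25 = county.loc[county["component"] == "PM25",
                      ["county_id", "year", "mean_concentration"]]
    pm25 = pm25.rename(columns={"mean_concentration": "pm25_mean"})
    county = county.merge(pm25, on=["county_id", "year"], how="left")
    is_metal = county["component"] != "PM25"
    with np.errstate(divide="ignore", invalid="ignore"):
        county["mass_proportion"] = np.where(
            is_metal & county["pm25_mean"].gt(0),
            county["mean_concentration"] / (county["pm25_mean"] * UG_TO_NG),
            np.nan,
        )
    return county.drop(columns=["pm25_mean"])


def urban_nonurban_ratio(
    county_exposures: pd.DataFrame,
    component: str,
    mode: str = "concentration",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Mean urban / mean nonurban exposure for one component, with bootstrap CI.

    Counties are resampled with replacement independently within the urban and
    nonurban strata; the CI is the 2.5/97.5 percentile of the replicate ratios.
    """
    if mode == "concentration":
        col = "mean_concentration"
    elif mode == "mass_proportion":
        col = "mass_proportion"
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    sub = county_exposures.loc[
        (county_exposures["component"] == component)
        & county_exposures[col].notna()
    ]
    urban = sub.loc[sub["urban"].astype(bool), col].to_numpy(dtype=float)
    rural = sub.loc[~sub["urban"].astype(bool), col].to_numpy(dtype=float)
    if len(urban) == 0:
        raise InsufficientDataError(f"no urban counties for {component}")
    if len(rural) == 0:
        raise InsufficientDataError(f"no nonurban counties for {component}")
    point = float(urban.mean() / rural.mean())
    rng = np.random.default_rng(seed)
    bu = urban[rng.integers(0, len(urban), size=(n_boot, len(urban)))].mean(axis=1)
    br = rural[rng.integers(0, len(rural), size=(n_boot, len(rural)))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = bu / br
    ratios = ratios[np.isfinite(ratios)]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return point, float(lo), float(hi)
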