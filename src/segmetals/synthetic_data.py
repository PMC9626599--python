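"""Synthetic tract demographics and speciated monitor records with planted truth.

The generator emulates the two input shapes the pipeline ingests — ACS-style
census-tract demographic tables and CSN/IMPROVE-style daily speciated PM2.5
monitor records — with a known, planted data-generating process so every
downstream stage can be tested without downloads:

* Tract mosaics use a two-block construction controlled by a per-county
  ``mixing_theta`` in [0, 1]: a fraction theta of each minority group is
  packed into a dedicated tract, the remainder spread evenly, which makes the
  realised dissimilarity index interpolate from 0 (theta=0, perfect evenness)
  to 1 (theta=1, disjoint occupancy) and equal theta up to integer rounding.
* County annual mean concentrations follow a log-linear gradient in DI:
  log(mean_m) = alpha_m + beta_m*log(DI) + region_effect + N(0, sigma_annual),
  so the elasticities beta_m are recoverable by the association stage.
* Daily values are lognormal around the annual mean (mean-corrected, so the
  expectation equals the planted annual mean), on an every-third-day schedule
  (days 1, 4, ..., 364: 122 scheduled samples), with independent dropout.
* Below-detection-limit values are generated like any others and merely fall
  below the per-component MDL carried on each record; censoring is a
  downstream concern.

Randomness is hierarchical: one scenario seed feeds per-purpose,
per-county, per-component ``SeedSequence`` streams, so adding a component or
county does not perturb the draws of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidScenarioError
from .monitor_qc import COMPONENT_UNITS
from .segregation import dissimilarity_index

ALL_COMPONENTS = tuple(COMPONENT_UNITS)  # canonical order fixes RNG streams

#: Planted elasticities: percent change per 10% DI increase, converted to
#: beta = ln(1 + pct/100) / ln(1.1).  Anthropogenic metals carry the steeper
#: gradients, natural-source metals the shallower ones, PM2.5 in between.
_PCT_PER_10PCT = {
    "Cu": 10.0, "Zn": 11.0, "Ni": 12.0, "Cr": 10.0, "Pb": 9.0, "V": 16.0,
    "Fe": 7.0, "Mn": 5.0, "Ti": 4.0, "PM25": 5.0,
}
DEFAULT_BETA = {
    m: float(np.log1p(p / 100.0) / np.log(1.1)) for m, p in _PCT_PER_10PCT.items()
}
#: Intercepts: log of a typical annual mean at DI = 1 (ng/m3; ug/m3 for PM25).
_TYPICAL_MEAN_AT_DI1 = {
    "Cu": 3.0, "Zn": 8.0, "Ni": 0.8, "Cr": 0.5, "Pb": 3.0, "V": 0.8,
    "Fe": 80.0, "Mn": 3.0, "Ti": 3.0, "PM25": 9.0,
}
DEFAULT_ALPHA = {m: float(np.log(v)) for m, v in _TYPICAL_MEAN_AT_DI1.items()}
#: Per-component minimum detectable limits, same units as concentrations.
DEFAULT_MDL = {
    "Cu": 0.4, "Zn": 1.0, "Ni": 0.12, "Cr": 0.1, "Pb": 0.4, "V": 0.15,
    "Fe": 6.0, "Mn": 0.4, "Ti": 0.5, "PM25": 1.0,
}
DEFAULT_REGION_EFFECTS = {
    "Midwest": 0.0, "Northeast": 0.10, "South": 0.15, "West": -0.10,
}
DEFAULT_GROUP_FRACTIONS = {
    "NHW": 0.60, "NHB": 0.18, "Hispanic": 0.13, "Asian": 0.06,
    "NativeAmerican": 0.03,
}


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic dataset.

    Defaults mirror the monitored-county analysis the pipeline targets:
    233 monitored counties, every-third-day sampling, all nine trace metals
    plus PM2.5, between-county log-scale noise 0.3 and within-year daily
    noise 0.5.
    """

    n_counties: int = 233
    tracts_per_county: int = 20
    groups: tuple[str, ...] = tuple(DEFAULT_GROUP_FRACTIONS)
    group_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_FRACTIONS))
    mixing_theta: float | Sequence[float] | None = None  # None: U(0.02, 0.98)
    county_population: int = 100_000
    components: tuple[str, ...] = ALL_COMPONENTS
    alpha_m: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta_m: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    region_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_EFFECTS))
    sigma_annual: float = 0.3
    sigma_daily: float = 0.5
    mdl: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MDL))
    group_fraction_sd: float = 0.3  # per-county log-scale jitter of fractions
    missing_rate: float = 0.10
    invalid_rate: float = 0.0
    urban_fraction: float = 0.5
    monitors_per_county: int = 1
    year: int = 2019
    period: str = "2014-2018"
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 1 or self.tracts_per_county < 1:
            raise InvalidScenarioError("n_counties and tracts_per_county must be >= 1")
        if self.county_population <= 0:
            raise InvalidScenarioError("county_population must be positive")
        for name in ("missing_rate", "invalid_rate", "urban_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidScenarioError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_annual < 0 or self.sigma_daily < 0:
            raise InvalidScenarioError("noise SDs must be non-negative")
        if not {"NHW", "NHB"} <= set(self.groups):
            raise InvalidScenarioError("groups must include NHW and NHB")
        thetas = self.thetas()
        if thetas is not None and ((thetas < 0) | (thetas > 1)).any():
            raise InvalidScenarioError("mixing_theta must lie in [0, 1]")
        for m in self.components:
            if m not in self.alpha_m or m not in self.beta_m or m not in self.mdl:
                raise InvalidScenarioError(f"component {m!r} missing alpha/beta/mdl")

    def thetas(self) -> np.ndarray | None:
        """Per-county mixing parameter, or None when drawn from the seed."""
        if self.mixing_theta is None:
            return None
        t = np.atleast_1d(np.asarray(self.mixing_theta, dtype=float))
        if len(t) == 1:
            t = np.repeat(t, self.n_counties)
        if len(t) != self.n_counties:
            raise InvalidScenarioError(
                f"mixing_theta has {len(t)} entries for {self.n_counties} counties")
        return t

    def county_ids(self) -> list[str]:
        return [f"{i + 1:05d}" for i in range(self.n_counties)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["components"] = list(self.components)
        if isinstance(d["mixing_theta"], np.ndarray):
            d["mixing_theta"] = d["mixing_theta"].tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticScenario":
        d = dict(d)
        for key in ("groups", "components"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted generator parameters for recovery tests."""

    beta_m: dict[str, float]
    di_by_county: dict[str, float]
    true_annual_means: pd.DataFrame  # county_id, component, true_mean
    sigma_annual: float
    sigma_daily: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "beta_m": self.beta_m,
            "di_by_county": self.di_by_county,
            "true_annual_means": self.true_annual_means.to_dict(orient="records"),
            "sigma_annual": self.sigma_annual,
            "sigma_daily": self.sigma_daily,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["true_annual_means"] = pd.DataFrame(payload["true_annual_means"])
        return cls(**payload)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator on the scenario's hierarchical seed tree."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# purpose tags for the seed tree
_T_THETA, _T_COORD, _T_ANNUAL, _T_DAILY, _T_DEMOG = 0, 1, 2, 3, 4


def realized_thetas(scenario: SyntheticScenario) -> np.ndarray:
    """Per-county theta: configured values, or U(0.02, 0.98) from the seed."""
    t = scenario.thetas()
    if t is None:
        t = _rng(scenario.seed, _T_THETA).uniform(0.02, 0.98, scenario.n_counties)
    return t


def _even_group_total(population: int, fraction: float, n_tracts: int) -> int:
    """Group total rounded to a multiple of the tract count (>= n_tracts)."""
    per_tract = max(1, round(population * fraction / n_tracts))
    return per_tract * n_tracts


def generate_tracts(scenario: SyntheticScenario) -> pd.DataFrame:
    """ACS-style tract table with a controllable segregation level per county.

    Tract 0 of each county is the "packed" block: a fraction theta of every
    minority group lives there on top of its even share, while the reference
    NHW population is correspondingly displaced to the remaining tracts.
    theta=0 reproduces the county-level proportions in every tract (DI = 0);
    theta=1 separates minority and reference completely (DI = 1).
    Deterministic given the scenario seed.
    """
    if scenario.tracts_per_county < 2:
        raise InvalidScenarioError(
            "tracts_per_county must be >= 2 (single-tract counties are "
            "excluded from the analysis by rule)")
    T = scenario.tracts_per_county
    thetas = realized_thetas(scenario)
    rows = []
    for c, county_id in enumerate(scenario.county_ids()):
        theta = float(thetas[c])
        fractions = {g: scenario.group_fractions[g] for g in scenario.groups}
        if scenario.group_fraction_sd > 0:
            # counties differ in racial composition: log-scale jitter,
            # renormalised so fractions stay a composition
            eps = _rng(scenario.seed, _T_DEMOG, c).normal(
                scale=scenario.group_fraction_sd, size=len(scenario.groups))
            raw = {g: fractions[g] * np.exp(e)
                   for g, e in zip(scenario.groups, eps)}
            total = sum(raw.values())
            fractions = {g: v / total for g, v in raw.items()}
        totals = {
            g: _even_group_total(scenario.county_population, fractions[g], T)
            for g in scenario.groups
        }
        counts = {}
        for g, X in totals.items():
            if g == "NHW":
                # reference: displaced out of the packed tract
                y_block = round((1.0 - theta) * X / T)
                rest = X - y_block
                base, rem = divmod(rest, T - 1)
                others = [base + (1 if i < rem else 0) for i in range(T - 1)]
                counts[g] = [y_block] + others
            else:
                x_even = round((1.0 - theta) * X / T)
                x_block = X - (T - 1) * x_even
                counts[g] = [x_block] + [x_even] * (T - 1)
        for t in range(T):
            row = {
                "tract_id": f"{county_id}{t:04d}",
                "county_id": county_id,
                "period": scenario.period,
            }
            for g in scenario.groups:
                row[g] = counts[g][t]
            row["total"] = sum(counts[g][t] for g in scenario.groups)
            rows.append(row)
    return pd.DataFrame(rows)


def _assign_regions(lat: np.ndarray, lon: np.ndarray,
                    labels: Sequence[str]) -> np.ndarray:
    """Deterministic region labels from coordinates (quadrant-style split)."""
    labels = list(labels)
    if len(labels) == 1:
        return np.full(len(lat), labels[0])
    region = np.empty(len(lat), dtype=object)
    west = lon < -100
    south = (~west) & (lat < 37)
    northeast = (~west) & (~south) & (lon > -82)
    midwest = ~(west | south | northeast)
    quadrants = [midwest, northeast, south, west]
    names = ["Midwest", "Northeast", "South", "West"]
    for mask, name in zip(quadrants, names):
        region[mask] = name if name in labels else labels[0]
    return region


def county_frame(scenario: SyntheticScenario) -> pd.DataFrame:
    """Per-county fixed attributes: coordinates, region, urban flag."""
    n = scenario.n_counties
    rng = _rng(scenario.seed, _T_COORD)
    lat = rng.uniform(25.0, 49.0, n)
    lon = rng.uniform(-124.0, -67.0, n)
    region = _assign_regions(lat, lon, list(scenario.region_effects))
    n_urban = int(round(scenario.urban_fraction * n))
    urban = np.zeros(n, dtype=bool)
    urban[rng.permutation(n)[:n_urban]] = True
    return pd.DataFrame({
        "county_id": scenario.county_ids(),
        "latitude": lat, "longitude": lon,
        "region": region, "urban": urban,
    })


def sampling_schedule(year: int) -> pd.DatetimeIndex:
    """Every-third-day schedule: days of year 1, 4, 7, ... (122 dates)."""
    start = pd.Timestamp(year=year, month=1, day=1)
    days = np.arange(1, 366, 3)
    days = days[days <= (366 if start.is_leap_year else 365)]
    return start + pd.to_timedelta(days - 1, unit="D")


def true_annual_means(
    scenario: SyntheticScenario,
    di_by_county: Mapping[str, float],
    counties: pd.DataFrame,
    zero_di_policy: str | float | None = None,
) -> pd.DataFrame:
    """Planted county x component annual means on the log-linear DI gradient.

    ``zero_di_policy``: None raises on DI = 0 (the gradient takes log(DI));
    ``"exclude"`` drops such counties; a float substitutes that DI floor.
    """
    comp_index = {m: ALL_COMPONENTS.index(m) for m in scenario.components}
    region_eff = dict(scenario.region_effects)
    rows = []
    for c, county_id in enumerate(counties["county_id"]):
        if county_id not in di_by_county:
            continue
        di = float(di_by_county[county_id])
        if di <= 0:
            if zero_di_policy is None:
                raise DomainError(
                    f"county {county_id} has DI = 0; log(DI) is undefined "
                    "(pass zero_di_policy to exclude or floor)")
            if zero_di_policy == "exclude":
                continue
            di = float(zero_di_policy)
        reg = region_eff.get(str(counties["region"].iloc[c]), 0.0)
        for m in scenario.components:
            eps = _rng(scenario.seed, _T_ANNUAL, c, comp_index[m]).normal()
            log_mean = (scenario.alpha_m[m] + scenario.beta_m[m] * np.log(di)
                        + reg + scenario.sigma_annual * eps)
            rows.append({"county_id": county_id, "component": m,
                         "true_mean": float(np.exp(log_mean)), "di": di})
    return pd.DataFrame(rows)


def generate_monitor_records(
    scenario: SyntheticScenario,
    di_by_county: Mapping[str, float],
    zero_di_policy: str | float | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Daily monitor records with a planted DI-concentration relationship.

    Returns the record table (monitor_qc ingestion schema) and the
    :class:`SyntheticTruth` needed for recovery tests.  Daily values are
    lognormal with expectation equal to the planted annual mean; each
    scheduled sample is dropped independently with ``missing_rate``; values
    below the MDL are generated like any others and only flagged downstream.
    """
    counties = county_frame(scenario)
    truth_means = true_annual_means(scenario, di_by_county, counties,
                                    zero_di_policy)
    schedule = sampling_schedule(scenario.year)
    n_days = len(schedule)
    comp_index = {m: ALL_COMPONENTS.index(m) for m in scenario.components}
    sd = scenario.sigma_daily

    county_rows = counties.set_index("county_id")
    frames = []
    for (county_id, component), grp in truth_means.groupby(
            ["county_id", "component"], sort=True):
        c = int(county_id) - 1
        mi = comp_index[component]
        attrs = county_rows.loc[county_id]
        true_mean = float(grp["true_mean"].iloc[0])
        for mon in range(scenario.monitors_per_county):
            rng = _rng(scenario.seed, _T_DAILY, c, mon, mi)
            eps = rng.normal(size=n_days)
            conc = true_mean * np.exp(sd * eps - 0.5 * sd * sd)
            keep = rng.random(n_days) >= scenario.missing_rate
            valid = rng.random(n_days) >= scenario.invalid_rate
            frames.append(pd.DataFrame({
                "monitor_id": f"{county_id}-M{mon:02d}",
                "county_id": county_id,
                "date": schedule[keep],
                "component": component,
                "concentration": conc[keep],
                "mdl": scenario.mdl[component],
                "valid": valid[keep],
                "urban": bool(attrs["urban"]),
                "region": str(attrs["region"]),
                "latitude": float(attrs["latitude"]),
                "longitude": float(attrs["longitude"]),
            }))
    records = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=[
                   "monitor_id", "county_id", "date", "component",
                   "concentration", "mdl", "valid", "urban", "region",
                   "latitude", "longitude"]))
    truth = SyntheticTruth(
        beta_m={m: float(scenario.beta_m[m]) for m in scenario.components},
        di_by_county={k: float(v) for k, v in di_by_county.items()},
        true_annual_means=truth_means,
        sigma_annual=scenario.sigma_annual,
        sigma_daily=scenario.sigma_daily,
        seed=scenario.seed,
    )
    return records, truth


def generate_dataset(
    scenario: SyntheticScenario,
    zero_di_policy: str | float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Tracts, daily monitor records, and planted truth in one call.

    The realised DI driving the concentration gradient is evaluated on the
    generated tract mosaics (NHB vs NHW), not assumed equal to theta.
    """
    tracts = generate_tracts(scenario)
    di = {
        cid: dissimilarity_index(tracts, cid, "NHB", "NHW").di
        for cid in scenario.county_ids()
    }
    records, truth = generate_monitor_records(scenario, di, zero_di_policy)
    return tracts, records, truth
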