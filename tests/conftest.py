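"""Shared fixtures: small synthetic datasets and daily-record builders."""

import numpy as np
import pandas as pd
import pytest

from segmetals.synthetic_data import SyntheticScenario, generate_dataset


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A fast three-component scenario exercising every pipeline stage."""
    return SyntheticScenario(
        n_counties=30, tracts_per_county=8,
        components=("Pb", "Fe", "PM25"), seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    """(tracts, daily records, planted truth) for the small scenario."""
    return generate_dataset(small_scenario)


def make_daily_records(
    n_samples: int = 122,
    year: int = 2019,
    component: str = "Pb",
    concentration=2.0,
    mdl: float = 0.5,
    valid=True,
    monitor_id: str = "M1",
    county_id: str = "00001",
    urban: bool = True,
) -> pd.DataFrame:
    """Hand-built daily records on the every-third-day calendar."""
    dates = pd.Timestamp(year=year, month=1, day=1) + pd.to_timedelta(
        np.arange(0, 3 * n_samples, 3), unit="D")
    conc = np.broadcast_to(np.asarray(concentration, dtype=float),
                           (n_samples,)).copy()
    val = np.broadcast_to(np.asarray(valid, dtype=bool), (n_samples,)).copy()
    return pd.DataFrame({
        "monitor_id": monitor_id,
        "county_id": county_id,
        "date": dates,
        "component": component,
        "concentration": conc,
        "mdl": mdl,
        "valid": val,
        "urban": urban,
        "region": "South",
        "latitude": 35.0,
        "longitude": -90.0,
    })


def random_tract_county(rng: np.random.Generator, max_tracts: int = 5,
                        max_pop: int = 20) -> pd.DataFrame:
    """A random small county with non-degenerate NHB and NHW totals."""
    while True:
        n = rng.integers(2, max_tracts + 1)
        nhb = rng.integers(0, max_pop + 1, n)
        nhw = rng.integers(0, max_pop + 1, n)
        if nhb.sum() > 0 and nhw.sum() > 0:
            break
    return pd.DataFrame({
        "tract_id": [f"t{i}" for i in range(n)],
        "county_id": "c1",
        "period": "2014-2018",
        "NHB": nhb,
        "NHW": nhw,
        "total": nhb + nhw,
    })
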