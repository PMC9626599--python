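"""County-level residential segregation: dissimilarity index and categories.

The dissimilarity index (DI) measures the evenness component of racial
residential segregation between a minority and a reference group.  With a
county split into census tracts,

    D = 0.5 * sum_i | x_i / X  -  y_i / Y |

where ``x_i`` (``y_i``) is the minority (reference) population of tract *i*
and ``X`` (``Y``) the county totals.  D ranges from 0 (every tract mirrors the
county-level proportions) to 1 (the two groups occupy disjoint tracts) and can
be read as the fraction of the minority population that would have to relocate
to achieve perfect evenness.

Counties are then binned into racial-residential-segregation (RRS) categories,
either by fixed DI cut points or by empirical tertiles of a reference DI
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    CountyExcludedSignal,
    DomainError,
    UndefinedIndexSignal,
)

#: Canonical demographic group column labels (ACS-style summary table).
GROUP_LABELS = ("NHW", "NHB", "Hispanic", "Asian", "NativeAmerican")

#: RRS category labels, ordered from least to most segregated.
RRS_LABELS = ("well_integrated", "moderately_segregated", "highly_segregated")

#: Fixed DI cut points: [0, 0.3) / [0.3, 0.6) / [0.6, 1].
RRS_FIXED_THRESHOLDS = (0.3, 0.6)


@dataclass(frozen=True)
class DissimilarityResult:
    """DI for one county and one minority/reference pair."""

    county_id: str
    period: str
    minority_group: str
    reference_group: str
    di: float
    n_tracts: int
    minority_total: float
    reference_total: float


def dissimilarity_index(
    tracts: pd.DataFrame,
    county_id: str,
    minority_group: str = "NHB",
    reference_group: str = "NHW",
) -> DissimilarityResult:
    """Compute the dissimilarity index for one county.

    Parameters
    ----------
    tracts
        Tract demographics with columns ``tract_id``, ``county_id``,
        ``period`` and one population column per group.
    county_id
        County to evaluate (FIPS-style string).
    minority_group, reference_group
        Group column labels; NHB vs NHW by default.

    Raises
    ------
    CountyExcludedSignal
        Single-tract counties are excluded by rule rather than evaluated.
    UndefinedIndexSignal
        A zero minority or reference county total leaves D undefined
        (the formula divides by X and Y).
    """
    for g in (minority_group, reference_group):
        if g not in tracts.columns:
            raise ConfigurationError(f"unknown group label {g!r}")
    sub = tracts.loc[tracts["county_id"] == county_id]
    if len(sub) == 0:
        raise CountyExcludedSignal(county_id, "no tracts")
    if len(sub) < 2:
        raise CountyExcludedSignal(county_id, "single census tract")

    x = sub[minority_group].to_numpy(dtype=float)
    y = sub[reference_group].to_numpy(dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise DomainError(f"negative population count in county {county_id}")
    X = x.sum()
    Y = y.sum()
    if X <= 0:
        raise UndefinedIndexSignal(county_id, minority_group)
    if Y <= 0:
        raise UndefinedIndexSignal(county_id, reference_group)

    # algebraically 0.5 * sum|x_i/X - y_i/Y|; the cross-multiplied form keeps
    # integer populations exact in double precision (DI hits 0 and 1 exactly)
    di = 0.5 * np.abs(x * Y - y * X).sum() / (X * Y)
    # guard against fp drift just past the theoretical bound
    di = float(min(max(di, 0.0), 1.0))
    period = str(sub["period"].iloc[0]) if "period" in sub.columns else ""
    return DissimilarityResult(
        county_id=county_id,
        period=period,
        minority_group=minority_group,
        reference_group=reference_group,
        di=di,
        n_tracts=int(len(sub)),
        minority_total=float(X),
        reference_total=float(Y),
    )


def categorize_rrs(
    di: float,
    scheme: str = "fixed_thresholds",
    reference_dis: Sequence[float] | None = None,
) -> str:
    """Assign an RRS category to a DI value.

    ``fixed_thresholds`` uses the conventional cut points, left-closed:
    [0, 0.3) well integrated, [0.3, 0.6) moderately segregated, [0.6, 1]
    highly segregated.  ``tertiles`` uses the empirical 33.3/66.7 percentiles
    of ``reference_dis`` instead, for sensitivity analyses where the fixed
    labels poorly fit the sampled counties.
    """
    if not 0.0 <= di <= 1.0:
        raise DomainError(f"DI must lie in [0, 1], got {di}")
    if scheme == "fixed_thresholds":
        lo, hi = RRS_FIXED_THRESHOLDS
    elif scheme == "tertiles":
        if reference_dis is None or len(reference_dis) == 0:
            raise ConfigurationError("tertiles scheme requires non-empty reference_dis")
        lo, hi = np.percentile(np.asarray(reference_dis, dtype=float), [100 / 3, 200 / 3])
    else:
        raise ConfigurationError(f"unknown RRS scheme {scheme!r}")
    if di < lo:
        return RRS_LABELS[0]
    if di < hi:
        return RRS_LABELS[1]
    return RRS_LABELS[2]


def di_all_pairs(
    tracts: pd.DataFrame,
    minority_groups: Iterable[str] = ("NHB",),
    reference_group: str = "NHW",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dissimilarity index for every county and minority group.

    Returns ``(results, exclusions)``: one row per county x minority group in
    ``results``; counties excluded by rule or with an undefined index are
    tabulated in ``exclusions`` with their reason instead of failing the run.
    """
    minority_groups = list(minority_groups)
    for g in minority_groups + [reference_group]:
        if g not in tracts.columns:
            raise ConfigurationError(f"unknown group label {g!r}")
    rows, excluded = [], []
    for county_id in tracts["county_id"].drop_duplicates():
        for group in minority_groups:
            try:
                res = dissimilarity_index(tracts, county_id, group, reference_group)
            except CountyExcludedSignal as sig:
                excluded.append(
                    {"county_id": county_id, "minority_group": group,
                     "status": "excluded", "reason": sig.reason}
                )
            except UndefinedIndexSignal as sig:
                excluded.append(
                    {"county_id": county_id, "minority_group": group,
                     "status": "undefined", "reason": f"zero {sig.group} population"}
                )
            else:
                rows.append(res.__dict__)
    cols = list(DissimilarityResult.__dataclass_fields__)
    results = pd.DataFrame(rows, columns=cols)
    exclusions = pd.DataFrame(
        excluded, columns=["county_id", "minority_group", "status", "reason"]
    )
    return results, exclusions
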