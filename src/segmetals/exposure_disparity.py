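"""Population-weighted exposure means and relative disparity across RRS categories.

For each segregation category *i*, the population-weighted mean exposure is

    Y_i = sum_j P_j x_j / sum_j P_j

over the monitored counties *j* in that category, with P_j the county
population and x_j the county's annual mean concentration or PM2.5 mass
proportion.  The relative disparity across categories is the coefficient of
variation of the category means,

    RD = sqrt(Var(Y)) / mean(Y),

a scale-free measure: 0 means perfect equality of population-weighted
exposure across segregation levels, and values are directly comparable
between chemical components and years regardless of magnitude.

Confidence intervals come from a stratified bootstrap: counties are resampled
with replacement independently within each category (at the observed category
sizes by default), the category means and RD recomputed per replicate, and
the 2.5/97.5 percentiles reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .segregation import RRS_LABELS

__all__ = [
    "DisparitySummary",
    "population_weighted_mean",
    "relative_disparity",
    "ratio_of_category_means",
    "bootstrap_rd_ci",
    "disparity_summary",
]


@dataclass
class DisparitySummary:
    """Relative disparity for one component/year/mode with its bootstrap CI."""

    component: str
    year: int
    mode: str  # concentration | mass_proportion
    category_means: dict[str, float]
    rd: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    variance: str = "population"  # denominator convention used in Var(Y)
    n_counties: dict[str, int] = field(default_factory=dict)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"county_id", "population", "rrs_category", "x"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"county weight records missing columns {sorted(missing)}")
    if (records["population"] <= 0).any():
        raise DomainError("county populations must be positive")
    return records


def population_weighted_mean(records: pd.DataFrame, category: str) -> float:
    """Population-weighted mean exposure Y_i for one RRS category.

    ``records`` is a county-level table with columns ``county_id``,
    ``population``, ``rrs_category`` and exposure ``x``.
    """
    _check_records(records)
    sub = records.loc[records["rrs_category"] == category]
    if len(sub) == 0:
        raise InsufficientDataError(f"no counties in RRS category {category!r}")
    p = sub["population"].to_numpy(dtype=float)
    x = sub["x"].to_numpy(dtype=float)
    return float(np.dot(p, x) / p.sum())


def relative_disparity(
    category_means: Sequence[float] | Mapping[str, float],
    variance: str = "population",
) -> float:
    """Coefficient of variation of the category means: sqrt(Var(Y))/mean(Y).

    ``variance`` selects the Var(Y) denominator: ``"population"`` divides by
    the number of categories K (the default), ``"sample"`` by K-1.  With the
    usual three categories the two conventions differ by a fixed factor
    sqrt(3/2), so the choice is carried in output metadata.
    """
    if isinstance(category_means, Mapping):
        y = np.asarray(list(category_means.values()), dtype=float)
    else:
        y = np.asarray(category_means, dtype=float)
    if y.size < 2:
        raise InsufficientDataError("relative disparity needs >= 2 category means")
    if not np.all(np.isfinite(y)):
        raise DomainError("non-finite category mean")
    mu = y.mean()
    if mu <= 0:
        raise DomainError(f"mean of category means must be positive, got {mu}")
    ddof = {"population": 0, "sample": 1}.get(variance)
    if ddof is None:
        raise DomainError(f"unknown variance convention {variance!r}")
    return float(np.sqrt(y.var(ddof=ddof)) / mu)


def _stratum_boot_means(
    rng: np.random.Generator,
    p: np.ndarray,
    x: np.ndarray,
    n_boot: int,
    size: int,
) -> np.ndarray:
    """Population-weighted means of ``n_boot`` with-replacement resamples."""
    idx = rng.integers(0, len(x), size=(n_boot, size))
    pw = p[idx]
    return (pw * x[idx]).sum(axis=1) / pw.sum(axis=1)


def ratio_of_category_means(
    records: pd.DataFrame,
    cat_a: str,
    cat_b: str,
    weighting: str = "population",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Ratio of category-a to category-b mean exposure with a bootstrap CI.

    ``weighting="population"`` uses population-weighted means (Y_a / Y_b);
    ``"unweighted"`` uses plain arithmetic means.  The CI resamples counties
    with replacement independently within each category at its observed size
    and takes the 2.5/97.5 percentiles of the replicate ratios.
    """
    _check_records(records)
    if weighting not in ("population", "unweighted"):
        raise DomainError(f"unknown weighting {weighting!r}")
    parts = {}
    for cat in (cat_a, cat_b):
        sub = records.loc[records["rrs_category"] == cat]
        if len(sub) == 0:
            raise InsufficientDataError(f"no counties in RRS category {cat!r}")
        p = sub["population"].to_numpy(dtype=float)
        if weighting == "unweighted":
            p = np.ones_like(p)
        parts[cat] = (p, sub["x"].to_numpy(dtype=float))

    def wmean(p, x):
        return np.dot(p, x) / p.sum()

    denom = wmean(*parts[cat_b])
    if denom == 0:
        raise DomainError(f"category {cat_b!r} mean is zero")
    point = float(wmean(*parts[cat_a]) / denom)

    rng = np.random.default_rng(seed)
    boot_a = _stratum_boot_means(rng, *parts[cat_a], n_boot, len(parts[cat_a][1]))
    boot_b = _stratum_boot_means(rng, *parts[cat_b], n_boot, len(parts[cat_b][1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = boot_a / boot_b
    ratios = ratios[np.isfinite(ratios)]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return point, float(lo), float(hi)


def bootstrap_rd_ci(
    records: pd.DataFrame,
    n_boot: int = 10_000,
    stratum_sizes: Mapping[str, int] | None = None,
    seed: int | None = None,
    variance: str = "population",
    return_replicates: bool = False,
):
    """Stratified bootstrap percentile CI for the relative disparity.

    Each replicate resamples counties with replacement independently within
    each RRS category (at the observed per-category counts unless
    ``stratum_sizes`` overrides them), recomputes the population-weighted
    category means and the relative disparity, and the 2.5/97.5 percentiles
    of the replicate RD distribution form the CI.  Deterministic given
    ``seed``.
    """
    _check_records(records)
    categories = [c for c in RRS_LABELS if (records["rrs_category"] == c).any()]
    extra = sorted(set(records["rrs_category"]) - set(RRS_LABELS))
    categories += extra
    if len(categories) < 2:
        raise InsufficientDataError(
            f"stratified bootstrap needs >= 2 non-empty categories, got {categories}"
        )
    rng = np.random.default_rng(seed)
    boot_means = np.empty((n_boot, len(categories)))
    for k, cat in enumerate(categories):
        sub = records.loc[records["rrs_category"] == cat]
        size = len(sub) if stratum_sizes is None else int(stratum_sizes[cat])
        if size < 1:
            raise InsufficientDataError(f"RRS category {cat!r} has no counties")
        p = sub["population"].to_numpy(dtype=float)
        x = sub["x"].to_numpy(dtype=float)
        boot_means[:, k] = _stratum_boot_means(rng, p, x, n_boot, size)

    ddof = 0 if variance == "population" else 1
    mu = boot_means.mean(axis=1)
    sd = boot_means.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        rds = np.where(mu > 0, sd / mu, np.nan)
    rds = rds[np.isfinite(rds)]
    lo, hi = np.percentile(rds, [2.5, 97.5])
    if return_replicates:
        return float(lo), float(hi), rds
    return float(lo), float(hi)


def disparity_summary(
    records: pd.DataFrame,
    component: str,
    year: int,
    mode: str,
    n_boot: int = 10_000,
    seed: int | None = None,
    variance: str = "population",
) -> DisparitySummary:
    """Category means, relative disparity, and bootstrap CI in one record."""
    categories = [c for c in RRS_LABELS if (records["rrs_category"] == c).any()]
    means = {c: population_weighted_mean(records, c) for c in categories}
    rd = relative_disparity(means, variance=variance)
    lo, hi = bootstrap_rd_ci(
        records, n_boot=n_boot, seed=seed, variance=variance
    )
    counts = records["rrs_category"].value_counts().to_dict()
    return DisparitySummary(
        component=component,
        year=year,
        mode=mode,
        category_means=means,
        rd=rd,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=-1 if seed is None else int(seed),
        variance=variance,
        n_counties={c: int(counts.get(c, 0)) for c in categories},
    )
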