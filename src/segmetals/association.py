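"""Log-log association between the dissimilarity index and concentrations.

Ordinary least squares of log(concentration) on log(DI) at the county level.
The slope is an elasticity: a 10% (multiplicative) increase in DI predicts a
(1.1**beta - 1)*100 percent change in concentration, which is the headline
unit the results are reported in.  Optional extensions: urban/rural
stratification, categorical region fixed effects, and log-transformed
percent-NHB / percent-NHW composition covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Recognised covariate labels for :func:`fit_loglog`.
COVARIATE_LABELS = ("region_fixed_effects", "log_pct_nhb", "log_pct_nhw",
                    "pct_nhb", "pct_nhw")


@dataclass
class AssociationResult:
    component: str
    stratum: str  # all | urban | rural
    covariates: tuple[str, ...]
    beta: float
    beta_se: float
    pct_per_10pct_di: float
    ci_low: float  # percent scale
    ci_high: float
    p_value: float
    n_counties: int
    n_excluded: int = 0
    extra_params: dict[str, float] = field(default_factory=dict)


def pct_change_per_10pct_di(beta: float) -> float:
    """Percent change in concentration per 10% increase in DI: (1.1^b - 1)*100.

    Base-invariant: the elasticity from a log-log fit is the same whatever
    logarithm base was used, so this map applies unchanged.
    """
    if not np.isfinite(beta):
        raise DomainError(f"beta must be finite, got {beta}")
    return float((1.1 ** beta - 1.0) * 100.0)


def fit_loglog(
    data: pd.DataFrame,
    component: str = "",
    covariates: Sequence[str] = (),
    stratum: str = "all",
    value_col: str = "concentration",
    di_col: str = "di",
    log_base: float = np.e,
    robust: bool = False,
) -> AssociationResult:
    """OLS of log(concentration) on log(DI) with optional covariates.

    Parameters
    ----------
    data
        County-level table with ``value_col`` and ``di_col``; ``urban``
        (boolean) required when stratifying, ``region`` for fixed effects,
        ``pct_nhb`` / ``pct_nhw`` (percent, 0-100) for composition covariates.
    covariates
        Subset of ``region_fixed_effects``, ``log_pct_nhb``, ``log_pct_nhw``
        (log-transformed percent, so coefficients convert with the same
        (1.1^b - 1) map) or ``pct_nhb`` / ``pct_nhw`` untransformed.
    stratum
        ``all``, ``urban`` or ``rural``.
    robust
        Use HC1 heteroskedasticity-robust standard errors.

    Counties with non-positive DI or concentration cannot enter a log-log fit
    and are dropped with a logged count.
    """
    unknown = set(covariates) - set(COVARIATE_LABELS)
    if unknown:
        raise ConfigurationError(f"unknown covariate labels {sorted(unknown)}")
    if stratum not in ("all", "urban", "rural"):
        raise ConfigurationError(f"unknown stratum {stratum!r}")

    df = data
    if stratum != "all":
        if "urban" not in df.columns:
            raise ConfigurationError("stratified fit requires an 'urban' column")
        df = df.loc[df["urban"] == (stratum == "urban")]

    usable = (df[value_col] > 0) & (df[di_col] > 0)
    for cov in covariates:
        if cov in ("log_pct_nhb", "pct_nhb"):
            usable &= df["pct_nhb"] > 0 if cov.startswith("log") else df["pct_nhb"].notna()
        if cov in ("log_pct_nhw", "pct_nhw"):
            usable &= df["pct_nhw"] > 0 if cov.startswith("log") else df["pct_nhw"].notna()
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "fit_loglog[%s/%s]: excluded %d counties with non-positive values",
            component, stratum, n_excluded,
        )
    df = df.loc[usable]

    log = np.log if log_base == np.e else (lambda v: np.log(v) / np.log(log_base))
    y = log(df[value_col].to_numpy(dtype=float))
    X = pd.DataFrame({"log_di": log(df[di_col].to_numpy(dtype=float))}, index=df.index)
    for cov in covariates:
        if cov == "region_fixed_effects":
            dummies = pd.get_dummies(df["region"], prefix="region", dtype=float)
            # first region (alphabetical) is the baseline
            X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
        elif cov == "log_pct_nhb":
            X["log_pct_nhb"] = log(df["pct_nhb"].to_numpy(dtype=float))
        elif cov == "log_pct_nhw":
            X["log_pct_nhw"] = log(df["pct_nhw"].to_numpy(dtype=float))
        elif cov == "pct_nhb":
            X["pct_nhb"] = df["pct_nhb"].to_numpy(dtype=float)
        elif cov == "pct_nhw":
            X["pct_nhw"] = df["pct_nhw"].to_numpy(dtype=float)
    X = sm.add_constant(X, prepend=True)

    if len(df) < 3 or len(df) <= X.shape[1]:
        raise InsufficientDataError(
            f"{len(df)} usable counties for {X.shape[1]} parameters "
            f"(component={component!r}, stratum={stratum!r})"
        )

    model = sm.OLS(y, X.astype(float))
    res = model.fit(cov_type="HC1") if robust else model.fit()

    beta = float(res.params["log_di"])
    se = float(res.bse["log_di"])
    # elasticity is base-invariant only if both axes share the base, which
    # they do here; normalise se/p the same way for log10 fits
    ci_b_lo, ci_b_hi = res.conf_int().loc["log_di"]
    return AssociationResult(
        component=component,
        stratum=stratum,
        covariates=tuple(covariates),
        beta=beta,
        beta_se=se,
        pct_per_10pct_di=pct_change_per_10pct_di(beta),
        ci_low=pct_change_per_10pct_di(float(ci_b_lo)),
        ci_high=pct_change_per_10pct_di(float(ci_b_hi)),
        p_value=float(res.pvalues["log_di"]),
        n_counties=int(len(df)),
        n_excluded=n_excluded,
        extra_params={k: float(v) for k, v in res.params.items() if k != "log_di"},
    )


def association_table(
    data: pd.DataFrame,
    components: Sequence[str],
    strata: Sequence[str] = ("all", "urban", "rural"),
    covariate_sets: Sequence[Sequence[str]] = ((),),
    value_col: str = "concentration",
) -> pd.DataFrame:
    """One association fit per component x stratum x covariate set.

    ``data`` holds one row per county x component with a ``component``
    column.  Fits that fail for lack of data are skipped with a log notice.
    """
    rows = []
    for comp in components:
        sub = data.loc[data["component"] == comp]
        for stratum in strata:
            for covs in covariate_sets:
                try:
                    res = fit_loglog(
                        sub, component=comp, covariates=covs,
                        stratum=stratum, value_col=value_col,
                    )
                except InsufficientDataError as exc:
                    logger.info("skipping %s/%s/%s: %s", comp, stratum, covs, exc)
                    continue
                row = res.__dict__.copy()
                row["covariates"] = "+".join(covs) if covs else "none"
                row.pop("extra_params")
                rows.append(row)
    return pd.DataFrame(rows)
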