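"""Global and local Moran's I spatial autocorrelation with permutation tests.

Spatial weights are k-nearest-neighbour (default k=8) on great-circle
distance, row-standardised, which handles the irregular spacing of air
monitors without creating islands.  Global Moran's I is

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2

with z the mean-centred values and S0 the total weight; under the
randomisation null its expectation is -1/(n-1).  The local statistic is
I_i = (z_i / m2) * sum_j w_ij z_j with m2 = sum z^2 / n, so that
sum_i I_i = n * I for row-standardised weights.  Inference is by random
permutation (global) and conditional permutation holding z_i fixed (local),
with the (r+1)/(n_perm+1) p-value estimator.  Significant sites are labelled
HH / LL / HL / LH by the sign pattern of (z_i, spatial lag of z_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

EARTH_RADIUS_KM = 6371.0088


@dataclass
class SpatialWeights:
    """Row-standardised k-nearest-neighbour weights."""

    site_ids: np.ndarray          # (n,) labels
    neighbors: np.ndarray         # (n, k) int indices into site_ids
    weights: np.ndarray           # (n, k) non-negative, rows sum to 1
    k: int
    metric: str = "great_circle"

    @property
    def n(self) -> int:
        return len(self.site_ids)

    @property
    def s0(self) -> float:
        return float(self.weights.sum())

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag: row-standardised weighted average of neighbours."""
        return (self.weights * z[self.neighbors]).sum(axis=1)


@dataclass
class MoranResult:
    global_i: float
    expected_i: float
    p_permutation: float
    n_permutations: int
    seed: int | None
    local_i: np.ndarray | None = None
    local_p: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    site_ids: np.ndarray | None = None
    perm_i: np.ndarray = field(default=None, repr=False)


def great_circle_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise haversine distance matrix in kilometres."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def build_knn_weights(
    latitudes,
    longitudes,
    k: int = 8,
    site_ids=None,
) -> SpatialWeights:
    """k-nearest-neighbour weights on great-circle distance, weight 1/k each.

    Distance ties are broken deterministically by site order, so duplicate
    coordinates never make the neighbour sets seed-dependent.  Neighbour sets
    may be asymmetric (A nearest to B does not imply the reverse).
    """
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    n = len(lat)
    if site_ids is None:
        site_ids = np.arange(n)
    site_ids = np.asarray(site_ids)
    if n <= k:
        raise DomainError(f"need more than k={k} sites, got n={n}")
    if np.abs(lat).max() > 90 or np.abs(lon).max() > 180:
        raise DomainError("coordinates outside valid degree ranges")

    dist = great_circle_km(lat, lon)
    np.fill_diagonal(dist, np.inf)  # no self-neighbours
    order = np.arange(n)
    # lexsort: primary key distance, secondary key site order (tie-break)
    nbrs = np.empty((n, k), dtype=int)
    for i in range(n):
        idx = np.lexsort((order, dist[i]))
        nbrs[i] = idx[:k]
    weights = np.full((n, k), 1.0 / k)
    return SpatialWeights(site_ids=site_ids, neighbors=nbrs, weights=weights, k=k)


def _check_values(values: np.ndarray, w: SpatialWeights) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if len(z) != w.n:
        raise DomainError(f"{len(z)} values for {w.n} sites")
    if np.ptp(z) == 0:
        raise DomainError("values are constant; Moran's I is undefined")
    return z


def _global_i(z: np.ndarray, w: SpatialWeights) -> float:
    zc = z - z.mean()
    num = float((zc * w.lag(zc)).sum())
    return (w.n / w.s0) * num / float((zc ** 2).sum())


def moran_global(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with a one-sided permutation test.

    The p-value is the proportion of random relabelings whose I is at least
    the observed value, with the +1 continuity correction
    ``(r + 1) / (n_perm + 1)``.
    """
    z = _check_values(values, weights)
    obs = _global_i(z, weights)
    rng = np.random.default_rng(seed)
    zc = z - z.mean()
    denom = float((zc ** 2).sum())
    perm = np.empty(n_perm)
    perms = rng.permuted(np.tile(zc, (n_perm, 1)), axis=1)
    lags = (weights.weights[None, :, :] * perms[:, weights.neighbors]).sum(axis=2)
    perm = (weights.n / weights.s0) * (perms * lags).sum(axis=1) / denom
    p = (np.count_nonzero(perm >= obs) + 1) / (n_perm + 1)
    return MoranResult(
        global_i=float(obs),
        expected_i=-1.0 / (weights.n - 1),
        p_permutation=float(p),
        n_permutations=n_perm,
        seed=seed,
        perm_i=perm,
    )


def moran_local(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> MoranResult:
    """Local Moran's I with conditional permutation inference.

    For each site, z_i is held fixed and its k neighbour values are drawn
    (without replacement) from the remaining n-1 values; the one-sided
    p-value is taken toward the observed local statistic.  Sites with
    p < alpha are labelled HH / LL / HL / LH from the signs of
    (z_i, lag_i); others are 'ns'.  ``fdr=True`` applies a
    Benjamini-Hochberg adjustment before labelling.
    """
    z = _check_values(values, weights)
    n, k = weights.n, weights.k
    zc = z - z.mean()
    m2 = float((zc ** 2).sum()) / n
    lag = weights.lag(zc)
    local = zc * lag / m2

    rng = np.random.default_rng(seed)
    pvals = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        others = zc[all_idx != i]
        # k draws without replacement per permutation, via partial argsort
        u = rng.random((n_perm, n - 1))
        pick = np.argpartition(u, k - 1, axis=1)[:, :k]
        sim_lag = (weights.weights[i] * others[pick]).sum(axis=1)
        sim = zc[i] * sim_lag / m2
        if local[i] >= 0:
            r = np.count_nonzero(sim >= local[i])
        else:
            r = np.count_nonzero(sim <= local[i])
        pvals[i] = (r + 1) / (n_perm + 1)

    sig_p = _bh_adjust(pvals) if fdr else pvals
    labels = np.full(n, "ns", dtype=object)
    sig = sig_p < alpha
    hi = zc > 0
    hilag = lag > 0
    labels[sig & hi & hilag] = "HH"
    labels[sig & ~hi & ~hilag] = "LL"
    labels[sig & hi & ~hilag] = "HL"
    labels[sig & ~hi & hilag] = "LH"

    glob = moran_global(values, weights, n_perm=n_perm, seed=seed)
    return MoranResult(
        global_i=glob.global_i,
        expected_i=glob.expected_i,
        p_permutation=glob.p_permutation,
        n_permutations=n_perm,
        seed=seed,
        local_i=local,
        local_p=pvals,
        cluster_labels=labels,
        site_ids=weights.site_ids,
        perm_i=glob.perm_i,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def moran_result_frame(result: MoranResult) -> pd.DataFrame:
    """Per-site local Moran table (site, local I, p, cluster label)."""
    if result.local_i is None:
        raise InsufficientDataError("result carries no local statistics")
    return pd.DataFrame({
        "site_id": result.site_ids,
        "local_i": result.local_i,
        "p_value": result.local_p,
        "cluster": result.cluster_labels,
    })
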