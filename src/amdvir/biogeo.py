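"""Distance-based biogeography statistics.

Community matrices are Hellinger-transformed (environmental tables
z-standardized), turned into Bray-Curtis (or Euclidean) distance matrices,
and analysed with PCoA ordination, Mantel tests, pairwise Pearson
correlation with Benjamini-Hochberg FDR control, and distance-decay
regressions of similarity on log10 geographic distance with a 1-km
local/regional scale split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class DdrFit:
    overall_slope: float
    local_slope: float
    regional_slope: float
    p_values: dict = field(default_factory=dict)
    adjusted_r2: dict = field(default_factory=dict)
    breakpoint_km: float = 1.0
    n_pairs: dict = field(default_factory=dict)


def transform(matrix: pd.DataFrame, method: str) -> pd.DataFrame:
    """Hellinger (row-wise sqrt of relative abundance) or column z-scores.

    Zero rows under Hellinger and zero-variance columns under standardize
    come out as zeros.
    """
    if method == "hellinger":
        if (matrix.values < 0).any():
            raise ValueError("hellinger requires non-negative entries")
        sums = matrix.sum(axis=1)
        out = matrix.div(sums.replace(0, np.nan), axis=0).pow(0.5).fillna(0.0)
        return out
    if method == "standardize":
        sd = matrix.std(axis=0, ddof=1)
        out = (matrix - matrix.mean(axis=0)) / sd.replace(0, np.nan)
        return out.fillna(0.0)
    raise ValueError(f"unknown transform {method!r}")


def dissimilarity(matrix: pd.DataFrame, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis or Euclidean distances over rows (samples)."""
    X = matrix.to_numpy(float)
    if metric == "bray_curtis":
        if (X < 0).any():
            raise ValueError("bray-curtis requires non-negative entries")
        d = pdist(X, metric="braycurtis")
        if np.isnan(d).any():  # pairs of all-zero rows
            logger.warning("all-zero sample pair(s); Bray-Curtis set to 0")
            d = np.nan_to_num(d, nan=0.0)
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(matrix.index), squareform(d), metric)


def geographic_distance(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from decimal lat/lon."""
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates outside valid lat/lon ranges")
    la = np.radians(lat)[:, None]
    lo = np.radians(lon)[:, None]
    dlat = la - la.T
    dlon = lo - lo.T
    a = np.sin(dlat / 2) ** 2 + np.cos(la) * np.cos(la.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(coords.index), d, "haversine_km")


def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates analysis).

    Returns coordinates on the axes with positive eigenvalues (columns
    PC1, PC2, ... sorted by decreasing eigenvalue; each axis's sign fixed
    so its largest-magnitude loading is positive) and the full eigenvalue
    spectrum in decreasing order (negative eigenvalues reported but their
    axes dropped).
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-9 * max(1.0, float(np.abs(evals).max()))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=d.labels, columns=cols), evals


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r over the strictly-lower-triangle entries; significance by
    jointly permuting rows/columns of the second matrix ``n_perm`` times,
    one-sided p = (1 + #{perm r >= observed}) / (1 + n_perm).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices have mismatched labels")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test requires n >= 4")
    il = np.tril_indices(n, k=-1)
    x = d1.values[il]
    x = (x - x.mean()) / x.std()
    y = d2.values[il]
    r_obs = float(np.mean(x * (y - y.mean()) / y.std()))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = d2.values[np.ix_(p, p)][il]
        r = float(np.mean(x * (yp - yp.mean()) / yp.std()))
        if r >= r_obs:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def correlation_matrix_bh(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with BH-adjusted q-values.

    Returns (r, p, q) DataFrames over the columns of ``table``. BH step-up
    adjustment runs across all distinct variable pairs. Zero-variance
    variables come out as NaN rows/columns.
    """
    cols = list(table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    pvals, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            sub = table.iloc[:, [i, j]].dropna()
            x, y = sub.iloc[:, 0], sub.iloc[:, 1]
            if len(sub) < 3 or x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            if np.isfinite(pij):
                pvals.append(pij)
                pairs.append((i, j))
    q = p.copy()
    if pvals:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), qv in zip(pairs, qvals):
            q.iloc[i, j] = q.iloc[j, i] = qv
    return r, p, q


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    n = len(x)
    adj = 1 - (1 - res.rvalue**2) * (n - 1) / (n - 2) if n > 2 else np.nan
    return float(res.slope), float(res.pvalue), float(adj)


def ddr_fit(
    geo: DistanceMatrix,
    comm: DistanceMatrix,
    breakpoint_km: float = 1.0,
) -> DdrFit:
    """Distance-decay regression of community similarity on log10 distance.

    Similarity = 1 - dissimilarity; regressions run over all sample pairs
    (overall), pairs at distance <= ``breakpoint_km`` (local) and pairs
    beyond it (regional). Zero geographic distances are replaced by half
    the smallest positive distance before the log. Partitions with fewer
    than 3 pairs yield NaN slopes.
    """
    if geo.labels != comm.labels:
        raise ValueError("distance matrices have mismatched labels")
    il = np.tril_indices(len(geo.labels), k=-1)
    dist = geo.values[il].copy()
    sim = 1.0 - comm.values[il]
    positive = dist[dist > 0]
    if positive.size == 0:
        raise ValueError("all geographic distances are zero")
    if (dist == 0).any():
        logger.warning(
            "zero geographic distances replaced by half the minimum positive "
            "distance before log10"
        )
        dist[dist == 0] = positive.min() / 2
    logd = np.log10(dist)
    fit = DdrFit(np.nan, np.nan, np.nan, breakpoint_km=breakpoint_km)
    masks = {
        "overall": np.ones_like(dist, dtype=bool),
        "local": dist <= breakpoint_km,
        "regional": dist > breakpoint_km,
    }
    for name, mask in masks.items():
        fit.n_pairs[name] = int(mask.sum())
        if mask.sum() < 3 or np.std(logd[mask]) == 0:
            fit.p_values[name] = np.nan
            fit.adjusted_r2[name] = np.nan
            continue
        slope, pval, adj = _ols_slope(logd[mask], sim[mask])
        setattr(fit, f"{name}_slope", slope)
        fit.p_values[name] = pval
        fit.adjusted_r2[name] = adj
    return fit
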