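"""Spatial genetic analyses: correlograms, great-circle distances, Mantel test.

The multivariate spatial autocorrelation coefficient r follows the
Smouse–Peakall construction: the squared genetic distance matrix is
Gower-centred into a covariance-like matrix C, and for each geographic
distance class the coefficient is the ratio of the summed cross-products
c_ij over pairs in the class to the corresponding summed variance terms,

    r(k) = 2 sum_{i<j in k} c_ij / sum_{i<j in k} (c_ii + c_jj),

which is bounded by [-1, 1] and invariant to rescaling all genetic
distances.  Permutation p-values shuffle individual locations; bootstrap
intervals resample pairs within a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Correlogram", "geo_distances", "spatial_autocorrelogram", "mantel"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class Correlogram:
    class_size: float
    classes: np.ndarray  # upper bounds
    n_pairs: np.ndarray
    r: np.ndarray
    p_perm: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    x_intercept: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_upper_km": self.classes,
                "n_pairs": self.n_pairs,
                "r": self.r,
                "p_perm": self.p_perm,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def geo_distances(coords: dict[str, tuple[float, float]] | pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km between named points."""
    if isinstance(coords, pd.DataFrame):
        coords = {
            str(r["deme"]): (float(r["lat"]), float(r["lon"]))
            for _, r in coords.iterrows()
        }
    names = list(coords)
    lat = np.radians([coords[n][0] for n in names])
    lon = np.radians([coords[n][1] for n in names])
    if (np.abs(np.degrees(lat)) > 90).any() or (np.abs(np.degrees(lon)) > 180).any():
        raise ValueError("coordinates out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=names, columns=names)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _class_r(c: np.ndarray, mask: np.ndarray) -> float:
    iu = np.triu_indices(c.shape[0], k=1)
    sel = mask[iu]
    if not sel.any():
        return np.nan
    num = 2.0 * c[iu][sel].sum()
    diag = np.diag(c)
    den = (diag[iu[0]][sel] + diag[iu[1]][sel]).sum()
    if den == 0:
        return np.nan
    return float(num / den)


def spatial_autocorrelogram(
    gdist: np.ndarray,
    geo: np.ndarray,
    class_size_km: float,
    n_perm: int = 999,
    n_boot: int = 1000,
    seed: int | None = None,
) -> Correlogram:
    """Multivariate autocorrelogram by geographic distance class.

    ``gdist`` holds squared genetic distances between individuals (site
    differences), ``geo`` geographic distances in km.  Distance classes are
    half-open intervals (lower, upper] of width ``class_size_km``.
    """
    gdist = np.asarray(gdist, dtype=float)
    geo = np.asarray(geo, dtype=float)
    if gdist.shape != geo.shape or gdist.shape[0] != gdist.shape[1]:
        raise ValueError("matrices must be square and conformable")
    if class_size_km <= 0:
        raise ValueError("class size must be positive")
    n = gdist.shape[0]
    rng = np.random.default_rng(seed)
    c = _gower_center(gdist)
    upper = np.arange(class_size_km, geo.max() + class_size_km, class_size_km)
    masks = [
        (geo > ub - class_size_km) & (geo <= ub) if ub > class_size_km
        else (geo >= 0) & (geo <= ub)
        for ub in upper
    ]
    iu = np.triu_indices(n, k=1)
    n_pairs = np.array([m[iu].sum() for m in masks])
    r = np.array([_class_r(c, m) for m in masks])

    # permutation: shuffle individual locations (rows/cols of geo)
    exceed = np.zeros(len(masks))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        geo_p = geo[np.ix_(perm, perm)]
        for k, ub in enumerate(upper):
            lb = ub - class_size_km
            m = (geo_p > lb) & (geo_p <= ub) if k else (geo_p <= ub)
            rp = _class_r(c, m)
            if not np.isnan(rp) and not np.isnan(r[k]) and rp >= r[k] - 1e-12:
                exceed[k] += 1
    p_perm = np.where(np.isnan(r), np.nan, (exceed + 1) / (n_perm + 1))

    # bootstrap: resample pairs within each class
    ci_low = np.full(len(masks), np.nan)
    ci_high = np.full(len(masks), np.nan)
    diag = np.diag(c)
    cross = c[iu]
    vsum = diag[iu[0]] + diag[iu[1]]
    for k, m in enumerate(masks):
        sel = np.where(m[iu])[0]
        if len(sel) < 2 or np.isnan(r[k]) or n_boot == 0:
            continue
        reps = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.choice(sel, size=len(sel), replace=True)
            den = vsum[take].sum()
            reps[b] = 2.0 * cross[take].sum() / den if den else np.nan
        ci_low[k], ci_high[k] = np.nanpercentile(reps, [2.5, 97.5])

    x_int = _x_intercept(upper, class_size_km, r)
    return Correlogram(
        class_size=class_size_km, classes=upper, n_pairs=n_pairs, r=r,
        p_perm=p_perm, ci_low=ci_low, ci_high=ci_high, x_intercept=x_int,
    )


def _x_intercept(upper: np.ndarray, width: float, r: np.ndarray) -> float | None:
    mid = upper - width / 2.0
    ok = ~np.isnan(r)
    mid, rv = mid[ok], r[ok]
    for k in range(len(rv) - 1):
        if rv[k] > 0 and rv[k + 1] <= 0:
            frac = rv[k] / (rv[k] - rv[k + 1])
            return float(mid[k] + frac * (mid[k + 1] - mid[k]))
    return None


def mantel(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two symmetric matrices.

    R is the Pearson correlation of the off-diagonal elements; the p-value
    is the one-sided proportion of simultaneous row/column permutations of
    ``m2`` with R at least the observed.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    k = m1.shape[0]
    if m1.shape != m2.shape or k < 3:
        raise ValueError("need conformable square matrices with k >= 3")
    iu = np.triu_indices(k, k=1)
    x, y = m1[iu], m2[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) matrix in Mantel test")
    robs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = m2[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, yp)[0, 1] >= robs - 1e-12:
            count += 1
    return robs, (count + 1) / (n_perm + 1)
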