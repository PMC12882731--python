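"""Ordinary kriging with a spherical variogram.

Turns discrete NDVI point predictions into continuous grids. The spherical
semivariogram

    gamma(h) = nugget + psill * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    gamma(h) = nugget + psill                              for h > a
    gamma(0) = 0

is fitted to the empirical semivariogram by pair-count-weighted least
squares, and each grid pixel is predicted as the weight sum
f~(p0) = sum_k w_k f(p_k) with the weights solving the ordinary-kriging
system under the unbiasedness constraint sum_k w_k = 1 (Lagrange
multiplier). Distances are planar Euclidean in degrees, adequate at the
desk scale of the synthetic domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .raster import Grid2D

__all__ = [
    "SamplePoints",
    "VariogramModel",
    "empirical_semivariogram",
    "spherical_gamma",
    "fit_spherical",
    "krige_grid",
    "kriging_weights",
]


class InsufficientDataError(ValueError):
    """Too few points or variogram bins for the requested operation."""


@dataclass(frozen=True)
class SamplePoints:
    """Scattered observations f(p_k) at lon/lat locations p_k."""

    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lon = np.asarray(self.lon, dtype=float).ravel()
        lat = np.asarray(self.lat, dtype=float).ravel()
        val = np.asarray(self.values, dtype=float).ravel()
        if not (lon.size == lat.size == val.size) or lon.size < 1:
            raise ValueError("lon, lat, values must be equal-length, non-empty")
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "values", val)

    @property
    def m(self) -> int:
        return self.lon.size

    def coords(self) -> np.ndarray:
        return np.column_stack([self.lon, self.lat])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"lon": self.lon, "lat": self.lat, "value": self.values}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SamplePoints":
        df = pd.read_csv(path)
        return cls(lon=df["lon"].to_numpy(), lat=df["lat"].to_numpy(),
                   values=df["value"].to_numpy())


@dataclass(frozen=True)
class VariogramModel:
    nugget: float
    partial_sill: float
    range_: float
    family: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("require nugget, partial_sill >= 0 and range > 0")
        if not np.all(np.isfinite([self.nugget, self.partial_sill, self.range_])):
            raise ValueError("variogram parameters must be finite")
        if self.family != "spherical":
            raise ValueError("only the spherical family is supported")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def spherical_gamma(h: np.ndarray | float, model: VariogramModel) -> np.ndarray | float:
    """Spherical semivariogram value(s) at distance(s) h >= 0; gamma(0) = 0."""
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0):
        raise ValueError("distance must be nonnegative")
    u = np.minimum(harr / model.range_, 1.0)
    g = model.nugget + model.partial_sill * (1.5 * u - 0.5 * u**3)
    g = np.where(harr > model.range_, model.nugget + model.partial_sill, g)
    g = np.where(harr == 0, 0.0, g)
    return float(g) if np.isscalar(h) else g


def empirical_semivariogram(points: SamplePoints, n_lags: int = 12,
                            max_dist: float | None = None,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram.

    gamma(h) in each bin is the average of 0.5 (f(p_a) - f(p_b))^2 over
    point pairs whose separation falls in the bin. Returns (lag centers,
    gamma estimates, pair counts); empty bins carry gamma = NaN.
    """
    if points.m < 2:
        raise InsufficientDataError("need at least two points")
    xy = points.coords()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(points.m, k=1)
    dist = d[iu]
    if max_dist is None:
        max_dist = float(dist.max())
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    sq = 0.5 * (points.values[:, None] - points.values[None, :]) ** 2
    gam_pairs = sq[iu]
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(dist, edges[1:-1])
    inside = dist <= max_dist
    gamma = np.full(n_lags, np.nan)
    counts = np.zeros(n_lags, dtype=int)
    for b in range(n_lags):
        sel = inside & (which == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = float(gam_pairs[sel].mean())
    return centers, gamma, counts


def fit_spherical(lag_centers: np.ndarray, gamma: np.ndarray,
                  counts: np.ndarray | None = None) -> VariogramModel:
    """Fit a spherical model by pair-count-weighted least squares.

    Needs at least three populated bins. Nonnegativity of nugget and
    partial sill is enforced by bounds; the range is bounded by twice the
    largest lag.
    """
    h = np.asarray(lag_centers, dtype=float)
    g = np.asarray(gamma, dtype=float)
    w = np.ones_like(h) if counts is None else np.asarray(counts, dtype=float)
    ok = np.isfinite(g) & (w > 0)
    if ok.sum() < 3:
        raise InsufficientDataError("need at least 3 populated variogram bins")
    h, g, w = h[ok], g[ok], np.sqrt(w[ok])

    if np.allclose(g, 0.0):
        return VariogramModel(nugget=0.0, partial_sill=0.0, range_=float(h.max()))

    def resid(theta):
        nug, psill, rng = theta
        m = VariogramModel(nugget=max(nug, 0.0), partial_sill=max(psill, 0.0),
                           range_=max(rng, 1e-12))
        return w * (np.asarray(spherical_gamma(h, m)) - g)

    sill0 = float(g[-3:].mean())
    x0 = np.array([max(g[0] * 0.5, 1e-6), max(sill0 - g[0] * 0.5, 1e-6),
                   float(h.max()) * 0.5])
    hi = np.array([sill0 * 2 + 1e-6, sill0 * 4 + 1e-6, float(h.max()) * 2])
    lo = np.array([0.0, 0.0, 1e-12])
    x0 = np.clip(x0, lo, hi * (1 - 1e-9))
    sol = least_squares(resid, x0, bounds=(lo, hi))
    nug, psill, rng = sol.x
    return VariogramModel(nugget=float(max(nug, 0.0)),
                          partial_sill=float(max(psill, 0.0)),
                          range_=float(rng))


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def _check_distinct(points: SamplePoints) -> None:
    xy = points.coords()
    _, counts = np.unique(np.round(xy, 12), axis=0, return_counts=True)
    if np.any(counts > 1):
        raise np.linalg.LinAlgError(
            "duplicate sample coordinates make the kriging system singular; "
            "deduplicate the points first")


def _ok_matrix(points: SamplePoints, model: VariogramModel) -> np.ndarray:
    m = points.m
    xy = points.coords()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = spherical_gamma(d, model)
    A[m, :m] = 1.0
    A[:m, m] = 1.0
    A[m, m] = 0.0
    return A


def kriging_weights(points: SamplePoints, model: VariogramModel,
                    target_lon: float, target_lat: float,
                    ) -> tuple[np.ndarray, float]:
    """Ordinary-kriging weights and Lagrange multiplier for one location."""
    _check_distinct(points)
    if points.m == 1:
        return np.array([1.0]), 0.0
    A = _ok_matrix(points, model)
    d0 = np.sqrt((points.lon - target_lon) ** 2 + (points.lat - target_lat) ** 2)
    b = np.empty(points.m + 1)
    b[:-1] = spherical_gamma(d0, model)
    b[-1] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular ordinary-kriging system ({points.m} points): {exc}") from exc
    return sol[:-1], float(sol[-1])


def krige_grid(points: SamplePoints, model: VariogramModel, target: Grid2D,
               max_global: int = 500, k_neighbors: int = 64) -> Grid2D:
    """Predict a full grid by ordinary kriging.

    Uses a single global system (one factorization, all target pixels)
    when m <= ``max_global``; above that each pixel uses its
    ``k_neighbors`` nearest sample points. With nugget = 0 the surface is
    exact at sample locations.
    """
    _check_distinct(points)
    LON, LAT = target.pixel_centers()
    lon_t, lat_t = LON.ravel(), LAT.ravel()
    m = points.m
    if m == 1:
        vals = np.full(target.shape, points.values[0], dtype=float)
        return target.with_values(vals, nodata=None)

    if m <= max_global:
        A = _ok_matrix(points, model)
        d0 = np.sqrt((lon_t[:, None] - points.lon[None, :]) ** 2
                     + (lat_t[:, None] - points.lat[None, :]) ** 2)
        B = np.empty((lon_t.size, m + 1))
        B[:, :m] = spherical_gamma(d0, model)
        B[:, m] = 1.0
        try:
            W = np.linalg.solve(A, B.T).T       # (n_pix, m+1)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular ordinary-kriging system ({m} points): {exc}") from exc
        pred = W[:, :m] @ points.values
    else:
        from scipy.spatial import cKDTree
        tree = cKDTree(points.coords())
        k = min(k_neighbors, m)
        _, nbr = tree.query(np.column_stack([lon_t, lat_t]), k=k)
        pred = np.empty(lon_t.size)
        # group pixels sharing a neighbor set to reuse factorizations
        order = np.lexsort(nbr.T)
        nbr_sorted = nbr[order]
        start = 0
        for i in range(1, lon_t.size + 1):
            if i == lon_t.size or not np.array_equal(nbr_sorted[i], nbr_sorted[start]):
                idx = nbr_sorted[start]
                sub = SamplePoints(lon=points.lon[idx], lat=points.lat[idx],
                                   values=points.values[idx])
                A = _ok_matrix(sub, model)
                pix = order[start:i]
                d0 = np.sqrt((lon_t[pix, None] - sub.lon[None, :]) ** 2
                             + (lat_t[pix, None] - sub.lat[None, :]) ** 2)
                B = np.empty((pix.size, k + 1))
                B[:, :k] = spherical_gamma(d0, model)
                B[:, k] = 1.0
                W = np.linalg.solve(A, B.T).T
                pred[pix] = W[:, :k] @ sub.values
                start = i
    return target.with_values(pred.reshape(target.shape), nodata=None)
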