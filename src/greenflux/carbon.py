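"""Wetland carbon sequestration and land-use change accounting.

Carbon sequestration potential of wetland vegetation is C = NPP * B with
the wetland carbon conversion factor B = 0.44 by default, evaluated over a
wetland mask (the water land-use class unless configured otherwise).

Land-use change between two epochs is summarized by the transfer matrix
T, whose element T_ij is the area (km²) of class i at the first epoch that
is class j at the second; the diagonal is the unchanged area. Change
statistics (net change, percent change with the first-epoch total as the
denominator, epoch shares) and pairwise conversion percentages follow.

A published 2020→2030 transfer matrix for a 2.71-million-km² six-class
domain ships as a packaged CSV fixture (see :func:`load_reference_matrix`)
and doubles as a regression oracle for the accounting functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import AlignmentError, Grid2D, LandUseGrid, MonthStack

__all__ = [
    "WetlandMask",
    "CarbonMap",
    "TransferMatrix",
    "ChangeStats",
    "ClassNppSummary",
    "extract_wetland_mask",
    "carbon_potential",
    "summarize_carbon",
    "transfer_matrix",
    "change_stats",
    "conversion_pct",
    "class_npp_stats",
    "load_reference_matrix",
]

B_WETLAND = 0.44  # wetland carbon conversion factor, gC per g


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class WetlandMask:
    grid: Grid2D  # boolean values

    @property
    def values(self) -> np.ndarray:
        return self.grid.values.astype(bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class CarbonMap:
    grid: Grid2D          # gC m-2 a-1, NaN outside the mask
    b_factor: float


@dataclass(frozen=True)
class TransferMatrix:
    """Cross-tabulated class areas (km²) between two epochs.

    ``marginal_t1``/``marginal_t2`` hold explicitly stated epoch totals
    (e.g. the Sum row/column of a published table, which can differ from
    the body sums in the last printed decimal); when present they are
    authoritative for the totals and must agree with the body within
    print-rounding tolerance.
    """

    labels: tuple[str, ...]
    areas: np.ndarray               # (n, n), km²
    epochs: tuple[str, str] = ("t1", "t2")
    cell_area_km2: float | None = None
    marginal_t1: np.ndarray | None = None
    marginal_t2: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError("areas must be square and match labels")
        if np.any(a < 0):
            raise ValueError("areas must be nonnegative")
        object.__setattr__(self, "areas", a)
        for name, marg, body in (("marginal_t1", self.marginal_t1, a.sum(axis=1)),
                                 ("marginal_t2", self.marginal_t2, a.sum(axis=0))):
            if marg is not None:
                m = np.asarray(marg, dtype=float)
                if m.shape != (n,):
                    raise ValueError(f"{name} must have one entry per class")
                # printed marginals may differ from body sums by rounding of
                # the printed cells only
                if not np.allclose(m, body, atol=0.005 * (2 * n), rtol=1e-9):
                    raise ValueError(f"{name} inconsistent with matrix body")
                object.__setattr__(self, name, m)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"class {label!r} not in transfer matrix") from None

    def t1_totals(self) -> np.ndarray:
        if self.marginal_t1 is not None:
            return self.marginal_t1.copy()
        return self.areas.sum(axis=1)

    def t2_totals(self) -> np.ndarray:
        if self.marginal_t2 is not None:
            return self.marginal_t2.copy()
        return self.areas.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.t1_totals().sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix with a trailing 'sum' row/column."""
        df = self.to_frame()
        df["sum"] = self.t1_totals()
        sums = np.append(self.t2_totals(), self.grand_total)
        df.loc["sum"] = sums
        df.index.name = "class"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path,
                 epochs: tuple[str, str] = ("t1", "t2")) -> "TransferMatrix":
        """Read a transfer CSV; a 'sum' row/column is kept as printed marginals."""
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("transfer CSV must have identical row/column classes")
        marg1 = marg2 = None
        if "sum" in df.columns:
            marg1 = df.loc[df.index != "sum", "sum"].to_numpy(float)
            marg2 = df.loc["sum", df.columns != "sum"].to_numpy(float)
            df = df.loc[df.index != "sum", df.columns != "sum"]
        return cls(labels=tuple(df.columns), areas=df.to_numpy(float),
                   epochs=epochs, marginal_t1=marg1, marginal_t2=marg2)


@dataclass(frozen=True)
class ChangeStats:
    """Per-class change summary derived from a transfer matrix.

    Percent change uses the first-epoch class total as denominator; a class
    absent at the first epoch gets NaN (flagged, not raised). Shares are
    percentages of the grand total at each epoch.
    """

    labels: tuple[str, ...]
    t1_area: np.ndarray
    t2_area: np.ndarray
    net_change: np.ndarray
    pct_change: np.ndarray
    t1_share_pct: np.ndarray
    t2_share_pct: np.ndarray

    def row(self, label: str) -> dict[str, float]:
        i = self.labels.index(label)
        return {
            "t1_area": float(self.t1_area[i]),
            "t2_area": float(self.t2_area[i]),
            "net_change": float(self.net_change[i]),
            "pct_change": float(self.pct_change[i]),
            "t1_share_pct": float(self.t1_share_pct[i]),
            "t2_share_pct": float(self.t2_share_pct[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t1_area_km2": self.t1_area, "t2_area_km2": self.t2_area,
            "net_change_km2": self.net_change, "pct_change": self.pct_change,
            "t1_share_pct": self.t1_share_pct, "t2_share_pct": self.t2_share_pct,
        }, index=list(self.labels))


@dataclass(frozen=True)
class ClassNppSummary:
    labels: tuple[str, ...]
    mean_npp: np.ndarray       # gC m-2 a-1, mean over years
    rate: np.ndarray           # OLS slope of class-mean NPP vs year
    yearly_means: pd.DataFrame  # (years x classes)


# ---------------------------------------------------------------------------
# Wetland carbon
# ---------------------------------------------------------------------------

def extract_wetland_mask(landuse: LandUseGrid,
                         wetland_classes: Sequence[str] = ("water",),
                         ) -> WetlandMask:
    """Mask of the cells whose land-use class is in ``wetland_classes``."""
    codes = [landuse.code_of(name) for name in wetland_classes]
    mask = np.isin(landuse.values, codes) & landuse.grid.mask()
    return WetlandMask(grid=landuse.grid.with_values(mask, nodata=None))


def carbon_potential(npp: Grid2D, mask: WetlandMask, b: float = B_WETLAND
                     ) -> CarbonMap:
    """C = NPP * B inside the wetland mask; NaN (nodata) outside."""
    if b <= 0:
        raise ValueError("B must be positive")
    if not npp.same_grid(mask.grid):
        raise AlignmentError("NPP grid and wetland mask are not aligned")
    inside = mask.values & npp.mask()
    c = np.where(inside, npp.values * b, np.nan)
    return CarbonMap(grid=npp.with_values(c, nodata=float("nan")), b_factor=b)


def summarize_carbon(carbon: CarbonMap) -> tuple[float, float, float]:
    """(min, max, mean) of the carbon map over masked, non-nodata pixels."""
    vals = carbon.grid.values
    ok = ~np.isnan(vals)
    if not ok.any():
        raise InsufficientDataError("empty wetland mask: no carbon pixels")
    v = vals[ok]
    return float(v.min()), float(v.max()), float(v.mean())


# ---------------------------------------------------------------------------
# Transfer matrix and change statistics
# ---------------------------------------------------------------------------

def transfer_matrix(lu1: LandUseGrid, lu2: LandUseGrid, cell_area_km2: float,
                    epochs: tuple[str, str] = ("t1", "t2")) -> TransferMatrix:
    """T_ij = area of cells with class i at t1 and class j at t2."""
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if dict(lu1.legend) != dict(lu2.legend):
        raise ValueError("the two epochs must share one legend")
    if not lu1.grid.same_grid(lu2.grid):
        raise AlignmentError("land-use grids are not aligned")
    codes = sorted(lu1.legend)
    labels = tuple(lu1.legend[c] for c in codes)
    pos = {c: i for i, c in enumerate(codes)}
    ok = lu1.grid.mask() & lu2.grid.mask()
    a = np.asarray(lu1.values)[ok].astype(int)
    b = np.asarray(lu2.values)[ok].astype(int)
    n = len(codes)
    counts = np.zeros((n, n), dtype=np.int64)
    flat = np.fromiter((pos[x] for x in a), int, a.size) * n \
        + np.fromiter((pos[x] for x in b), int, b.size)
    binned = np.bincount(flat, minlength=n * n)
    counts += binned.reshape(n, n)
    return TransferMatrix(labels=labels, areas=counts * float(cell_area_km2),
                          epochs=epochs, cell_area_km2=float(cell_area_km2))


def change_stats(T: TransferMatrix) -> ChangeStats:
    t1 = T.t1_totals()
    t2 = T.t2_totals()
    net = t2 - t1
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(t1 > 0, 100.0 * net / t1, np.nan)
    g = T.grand_total
    return ChangeStats(labels=T.labels, t1_area=t1, t2_area=t2, net_change=net,
                       pct_change=pct, t1_share_pct=100.0 * t1 / g,
                       t2_share_pct=100.0 * t2 / g)


def conversion_pct(T: TransferMatrix, from_class: str, to_class: str,
                   denom_class: str | None = None, denom_epoch: str = "t1",
                   ) -> float:
    """Converted area T[from, to] as a percent of a class total.

    The denominator defaults to the ``from_class`` total at the first
    epoch; a different reference class or the second epoch can be named.
    Returns NaN when the denominator total is zero.
    """
    i, j = T.index(from_class), T.index(to_class)
    d = T.index(denom_class) if denom_class is not None else i
    if denom_epoch == "t1":
        denom = T.t1_totals()[d]
    elif denom_epoch == "t2":
        denom = T.t2_totals()[d]
    else:
        raise ValueError("denom_epoch must be 't1' or 't2'")
    if denom == 0:
        return float("nan")
    return float(100.0 * T.areas[i, j] / denom)


def load_reference_matrix() -> TransferMatrix:
    """The packaged published 2020→2030 six-class transfer matrix (km²)."""
    ref = resources.files("greenflux.data") / "landuse_transfer_2020_2030.csv"
    with resources.as_file(ref) as path:
        return TransferMatrix.from_csv(path, epochs=("2020", "2030"))


# ---------------------------------------------------------------------------
# Per-class NPP summaries
# ---------------------------------------------------------------------------

def class_npp_stats(annual_npp_by_year: Mapping[int, Grid2D],
                    landuse: LandUseGrid) -> ClassNppSummary:
    """Class-mean annual NPP per year, overall mean, and OLS trend.

    The rate is the least-squares slope of the class-mean series against
    the calendar year (gC m-2 a-1 per year). Classes absent from the grid
    are omitted.
    """
    years = sorted(annual_npp_by_year)
    if not years:
        raise InsufficientDataError("no annual NPP maps given")
    codes = sorted(landuse.legend)
    lu_mask = landuse.grid.mask()
    rows = {}
    for code in codes:
        sel = lu_mask & (landuse.values == code)
        if not sel.any():
            import warnings
            warnings.warn(f"class {landuse.legend[code]!r} absent; omitted",
                          stacklevel=2)
            continue
        means = []
        for y in years:
            npp = annual_npp_by_year[y]
            if not npp.same_grid(landuse.grid):
                raise AlignmentError(f"annual NPP {y} not aligned with land use")
            ok = sel & npp.mask()
            means.append(float(npp.values[ok].mean()) if ok.any() else np.nan)
        rows[landuse.legend[code]] = means
    df = pd.DataFrame(rows, index=years)
    yr = np.asarray(years, dtype=float)
    labels = tuple(df.columns)
    mean_npp = df.mean(axis=0).to_numpy()
    if len(years) > 1:
        yc = yr - yr.mean()
        slopes = (df.to_numpy() * yc[:, None]).sum(axis=0) / (yc ** 2).sum()
    else:
        slopes = np.zeros(len(labels))
    return ClassNppSummary(labels=labels, mean_npp=mean_npp,
                           rate=np.asarray(slopes, dtype=float), yearly_means=df)
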