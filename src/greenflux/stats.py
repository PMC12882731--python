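"""Spearman rank correlation between climate drivers and NPP.

Pairs annual NPP with annual climate aggregates — precipitation summed,
the other drivers averaged over the year — either per (pixel, year) record
("pixel-annual", the default) or as domain-mean monthly series
("region-monthly"), then computes the full Spearman correlation matrix
with mid-rank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import ClimateCube, Grid2D

__all__ = [
    "PairedSeriesTable",
    "CorrelationMatrix",
    "pair_series",
    "spearman_rho",
    "correlation_matrix",
]

#: Variables in the correlation analysis, in display order.
CORR_VARS = ("precipitation", "temperature", "solar_radiation",
             "relative_humidity", "npp")

# how each climate variable aggregates from months to a year
_ANNUAL_AGG = {"precipitation": "sum", "temperature": "mean",
               "solar_radiation": "sum", "relative_humidity": "mean"}


class UndefinedStatisticError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSeriesTable:
    table: pd.DataFrame       # columns = CORR_VARS
    aggregation: str          # "pixel-annual" | "region-monthly"

    def __post_init__(self) -> None:
        missing = set(CORR_VARS) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.table.isna().any().any():
            raise ValueError("paired table must have no missing entries")


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        n = len(self.labels)
        if r.shape != (n, n):
            raise ValueError("rho must be square and match labels")
        object.__setattr__(self, "rho", r)

    def value(self, a: str, b: str) -> float:
        return float(self.rho[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=list(self.labels),
                            columns=list(self.labels))


def pair_series(climate: ClimateCube, annual_npp: Mapping[int, Grid2D],
                aggregation: str = "pixel-annual") -> PairedSeriesTable:
    """Build the aligned five-variable table for correlation analysis."""
    years = sorted({k[0] for k in climate.months} & set(annual_npp))
    if not years:
        raise InsufficientDataError("no overlapping years between climate and NPP")
    template = climate.template
    records = []
    if aggregation == "pixel-annual":
        for y in years:
            npp = annual_npp[y]
            if not npp.same_grid(template):
                raise ValueError(f"annual NPP {y} not aligned with climate")
            cols = {}
            for var, how in _ANNUAL_AGG.items():
                arr = climate[var].year(y).to_array()
                cols[var] = arr.sum(axis=0) if how == "sum" else arr.mean(axis=0)
            ok = npp.mask()
            rec = pd.DataFrame({v: cols[v][ok].ravel() for v in _ANNUAL_AGG})
            rec["npp"] = npp.values[ok].ravel()
            records.append(rec)
        table = pd.concat(records, ignore_index=True)
    elif aggregation == "region-monthly":
        # domain-mean monthly climate against the annual NPP spread evenly
        # over its year's months (monthly NPP is not retained at this level)
        rows = []
        for (y, m) in climate.months:
            if y not in annual_npp:
                continue
            row = {var: float(np.nanmean(climate[var][(y, m)].values))
                   for var in _ANNUAL_AGG}
            npp = annual_npp[y]
            row["npp"] = float(npp.values[npp.mask()].mean()) / 12.0
            rows.append(row)
        if not rows:
            raise InsufficientDataError("no overlapping months")
        table = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return PairedSeriesTable(table=table[list(CORR_VARS)], aggregation=aggregation)


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    rx, ry = _midranks(x), _midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    sx = np.sqrt((dx ** 2).sum())
    sy = np.sqrt((dy ** 2).sum())
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("Spearman rho undefined for constant series")
    return float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))


def correlation_matrix(table: PairedSeriesTable) -> CorrelationMatrix:
    """All pairwise Spearman correlations; symmetric with unit diagonal."""
    labels = tuple(table.table.columns)
    n = len(labels)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = spearman_rho(table.table.iloc[:, i].to_numpy(),
                             table.table.iloc[:, j].to_numpy())
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(labels=labels, rho=rho)
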