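"""CASA light-use-efficiency NPP model.

Monthly NPP per pixel is the product of absorbed photosynthetically active
radiation and the light-use efficiency:

    NPP(x,t)  = APAR(x,t) * eps(x,t)            [gC m-2 month-1]
    APAR(x,t) = SOL(x,t) * FPAR(x,t) * 0.5      [MJ m-2 month-1]
    FPAR      = 0.5 * (FPAR_NDVI + FPAR_SR)     clipped to [0.001, 0.95]

FPAR_NDVI rescales NDVI linearly from the per-vegetation-class NDVI bounds
to [FPAR_min, FPAR_max]; FPAR_SR does the same for the simple ratio
SR = (1 + NDVI) / (1 - NDVI), with SR bounds derived from the NDVI bounds.
Annual NPP is the pixelwise sum of the 12 monthly maps.

The light-use efficiency eps is a constant maximum by default (no stress
formulation is imposed), with an optional temperature/water stress-product
mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .raster import AlignmentError, Grid2D, LandUseGrid, MonthStack

__all__ = [
    "CasaParams",
    "ClassBounds",
    "simple_ratio",
    "class_ndvi_bounds",
    "fpar_ndvi",
    "fpar_sr",
    "combine_fpar",
    "apar",
    "epsilon",
    "monthly_npp",
    "annual_npp",
    "npp_from_ndvi",
]

FPAR_MAX = 0.95
FPAR_MIN = 0.001


@dataclass(frozen=True)
class ClassBounds:
    """Per-class NDVI min/max and the SR bounds derived from them."""

    ndvi_min: dict[int, float]
    ndvi_max: dict[int, float]

    def __post_init__(self) -> None:
        for c in self.ndvi_min:
            if not self.ndvi_min[c] < self.ndvi_max[c]:
                raise ValueError(f"class {c}: ndvi_min must be < ndvi_max")

    def sr_min(self, code: int) -> float:
        return float(_sr(np.asarray(self.ndvi_min[code])))

    def sr_max(self, code: int) -> float:
        return float(_sr(np.asarray(self.ndvi_max[code])))

    @property
    def classes(self) -> set[int]:
        return set(self.ndvi_min)


@dataclass(frozen=True)
class CasaParams:
    fpar_max: float = FPAR_MAX
    fpar_min: float = FPAR_MIN
    epsilon_max: float = 0.389          # gC MJ-1
    epsilon_mode: str = "constant"      # or "stress_product"
    ndvi_clamp: float = 0.98            # keep SR finite
    bounds_lower_pct: float = 5.0
    bounds_upper_pct: float = 95.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fpar_min < self.fpar_max <= 1.0:
            raise ValueError("require 0 <= fpar_min < fpar_max <= 1")
        if self.epsilon_max <= 0:
            raise ValueError("epsilon_max must be positive")
        if self.epsilon_mode not in ("constant", "stress_product"):
            raise ValueError(f"unknown epsilon_mode {self.epsilon_mode!r}")

    def to_yaml(self) -> str:
        import dataclasses
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CasaParams":
        return cls(**yaml.safe_load(text))


def _sr(ndvi: np.ndarray) -> np.ndarray:
    return (1.0 + ndvi) / (1.0 - ndvi)


def _require_aligned(a: Grid2D, b: Grid2D, what: str) -> None:
    if not a.same_grid(b):
        raise AlignmentError(f"{what}: grids are not aligned")


def simple_ratio(ndvi: Grid2D, clamp: float | None = 0.98) -> Grid2D:
    """SR = (1 + NDVI) / (1 - NDVI), with NDVI clamped below ``clamp``.

    Pass ``clamp=None`` to disable clamping, in which case NDVI >= 1 raises.
    """
    v = ndvi.values.astype(float)
    if clamp is not None:
        v = np.minimum(v, clamp)
    else:
        m = ndvi.mask()
        if np.any(v[m] >= 1.0):
            raise ValueError("NDVI >= 1 makes the simple ratio singular")
    return ndvi.with_values(_sr(v))


def class_ndvi_bounds(ndvi: MonthStack, landuse: LandUseGrid,
                      lower_pct: float = 5.0, upper_pct: float = 95.0,
                      min_pixels: int = 10) -> ClassBounds:
    """Per-class NDVI bounds as percentiles of the pooled class NDVI.

    A class with fewer than ``min_pixels`` pixels falls back to the global
    bounds (with a warning); degenerate (constant) bounds are widened by a
    minimal epsilon so downstream rescaling stays defined.
    """
    ref = ndvi.first
    _require_aligned(ref, landuse.grid, "class_ndvi_bounds")
    cube = ndvi.to_array()                      # (T, rows, cols)
    codes = landuse.values
    lu_mask = landuse.grid.mask()
    glo = cube[:, lu_mask].ravel()
    g_lo, g_hi = np.percentile(glo, [lower_pct, upper_pct])
    lo_d: dict[int, float] = {}
    hi_d: dict[int, float] = {}
    for code in sorted(landuse.legend):
        sel = lu_mask & (codes == code)
        n = int(sel.sum())
        if n == 0:
            continue
        if n < min_pixels:
            warnings.warn(
                f"class {landuse.legend[code]!r} has only {n} pixels; "
                "using global NDVI bounds", stacklevel=2)
            lo, hi = float(g_lo), float(g_hi)
        else:
            pool = cube[:, sel].ravel()
            lo, hi = (float(x) for x in np.percentile(pool, [lower_pct, upper_pct]))
        if hi - lo < 1e-9:
            warnings.warn(
                f"class {landuse.legend[code]!r} has degenerate NDVI bounds; "
                "widening by epsilon", stacklevel=2)
            lo, hi = lo - 5e-4, hi + 5e-4
        lo_d[code], hi_d[code] = lo, hi
    return ClassBounds(ndvi_min=lo_d, ndvi_max=hi_d)


def _rescale_by_class(vals: np.ndarray, codes: np.ndarray,
                      lo_by_class: dict[int, float], hi_by_class: dict[int, float],
                      params: CasaParams) -> np.ndarray:
    out = np.full(vals.shape, np.nan)
    present = np.unique(codes)
    missing = [int(c) for c in present if int(c) not in lo_by_class]
    if missing:
        raise KeyError(f"no bounds configured for class codes {missing}")
    for code in present:
        lo, hi = lo_by_class[int(code)], hi_by_class[int(code)]
        sel = codes == code
        frac = (vals[sel] - lo) / (hi - lo)
        out[sel] = params.fpar_min + frac * (params.fpar_max - params.fpar_min)
    return np.clip(out, params.fpar_min, params.fpar_max)


def fpar_ndvi(ndvi: Grid2D, landuse: LandUseGrid, bounds: ClassBounds,
              params: CasaParams = CasaParams()) -> Grid2D:
    """FPAR from NDVI: linear rescale of the class NDVI bounds onto
    [fpar_min, fpar_max], clipped to that interval."""
    _require_aligned(ndvi, landuse.grid, "fpar_ndvi")
    out = _rescale_by_class(ndvi.values.astype(float), landuse.values,
                            bounds.ndvi_min, bounds.ndvi_max, params)
    return ndvi.with_values(out)


def fpar_sr(sr: Grid2D, landuse: LandUseGrid, bounds: ClassBounds,
            params: CasaParams = CasaParams()) -> Grid2D:
    """FPAR from the simple ratio, rescaled between the class SR bounds."""
    _require_aligned(sr, landuse.grid, "fpar_sr")
    sr_lo = {c: bounds.sr_min(c) for c in bounds.classes}
    sr_hi = {c: bounds.sr_max(c) for c in bounds.classes}
    out = _rescale_by_class(sr.values.astype(float), landuse.values,
                            sr_lo, sr_hi, params)
    return sr.with_values(out)


def combine_fpar(f_ndvi: Grid2D, f_sr: Grid2D) -> Grid2D:
    """Equal-weight mean of the two FPAR estimates."""
    _require_aligned(f_ndvi, f_sr, "combine_fpar")
    return f_ndvi.with_values(0.5 * (f_ndvi.values + f_sr.values))


def apar(sol: Grid2D, fpar: Grid2D) -> Grid2D:
    """APAR = SOL * FPAR * 0.5 (MJ m-2 month-1).

    The 0.5 is the photosynthetically active fraction of total solar
    radiation.
    """
    _require_aligned(sol, fpar, "apar")
    if np.any(sol.valid_values() < 0):
        raise ValueError("solar radiation must be nonnegative")
    return sol.with_values(sol.values * fpar.values * 0.5)


def epsilon(temperature: Grid2D | None, moisture: Grid2D | None,
            params: CasaParams = CasaParams(),
            template: Grid2D | None = None) -> Grid2D:
    """Light-use efficiency field (gC MJ-1).

    constant mode: epsilon_max everywhere. stress_product mode:
    epsilon_max * s_T * s_W with a parabolic temperature response peaking
    at 15 degC and a saturating moisture response, each bounded in
    (0, 1.2].
    """
    if params.epsilon_mode == "constant":
        ref = template or temperature or moisture
        if ref is None:
            raise ValueError("constant mode needs a template grid")
        return ref.with_values(np.full(ref.shape, params.epsilon_max))
    if temperature is None or moisture is None:
        raise ValueError("stress_product mode needs temperature and moisture grids")
    _require_aligned(temperature, moisture, "epsilon")
    t = temperature.values.astype(float)
    w = moisture.values.astype(float)
    s_t = np.clip(1.0 - ((t - 15.0) / 25.0) ** 2, 0.05, 1.2)
    s_w = np.clip(0.5 + w / (w + 0.15), 0.05, 1.2)
    return temperature.with_values(params.epsilon_max * s_t * s_w)


def monthly_npp(apar_grid: Grid2D, eps: Grid2D) -> Grid2D:
    """NPP(x,t) = APAR(x,t) * eps(x,t), gC m-2 month-1."""
    _require_aligned(apar_grid, eps, "monthly_npp")
    return apar_grid.with_values(apar_grid.values * eps.values)


def annual_npp(months: MonthStack, year: int | None = None) -> Grid2D:
    """Pixelwise sum of the 12 monthly NPP maps of one year (gC m-2 a-1)."""
    if year is None:
        years = months.years
        if len(years) != 1:
            raise ValueError("stack spans several years; pass year explicitly")
        year = years[0]
    sub = months.year(year)   # raises if the year is incomplete
    return sub.first.with_values(sub.to_array().sum(axis=0))


def npp_from_ndvi(ndvi: MonthStack, sol: MonthStack, landuse: LandUseGrid,
                  params: CasaParams = CasaParams(),
                  bounds: ClassBounds | None = None,
                  temperature: MonthStack | None = None,
                  moisture: MonthStack | None = None,
                  ) -> tuple[MonthStack, dict[int, Grid2D], ClassBounds]:
    """Full CASA chain: NDVI + SOL (+ land use) -> monthly and annual NPP.

    Returns (monthly NPP stack, {year: annual NPP}, the class bounds used).
    """
    if not ndvi.aligned_with(sol):
        raise AlignmentError("NDVI and solar-radiation stacks are not aligned")
    if bounds is None:
        bounds = class_ndvi_bounds(ndvi, landuse,
                                   params.bounds_lower_pct, params.bounds_upper_pct)
    monthly: dict[tuple[int, int], Grid2D] = {}
    for key, nd in ndvi.items():
        nd_clamped = nd.with_values(np.minimum(nd.values, params.ndvi_clamp))
        sr = simple_ratio(nd_clamped, clamp=params.ndvi_clamp)
        f1 = fpar_ndvi(nd_clamped, landuse, bounds, params)
        f2 = fpar_sr(sr, landuse, bounds, params)
        fp = combine_fpar(f1, f2)
        ap = apar(sol[key], fp)
        if params.epsilon_mode == "constant":
            eps = epsilon(None, None, params, template=nd)
        else:
            eps = epsilon(temperature[key] if temperature else None,
                          moisture[key] if moisture else None, params)
        monthly[key] = monthly_npp(ap, eps)
    stack = MonthStack(monthly)
    annual = {y: annual_npp(stack, y) for y in stack.years
              if len([k for k in stack.keys() if k[0] == y]) == 12}
    return stack, annual, bounds
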