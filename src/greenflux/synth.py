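"""Synthetic climate, NDVI and land-use generator.

Emulates the statistical structure of the study inputs — spatially
autocorrelated monthly fields with a southeast-high / northwest-low
gradient, a seasonal cycle peaking in boreal summer, an NDVI produced by a
known monotone link to climate, and a six-class land-use legend — with the
generating truth stored alongside, so every downstream stage (network
skill, variogram recovery, correlation signs) can be tested against known
ground truth. Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .raster import (
    CLIMATE_VARS,
    ClimateCube,
    Grid2D,
    LANDUSE_CLASSES,
    LandUseGrid,
    MonthStack,
    month_range,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruthLink",
    "make_gaussian_field",
    "synth_climate",
    "synth_ndvi",
    "synth_landuse_pair",
]

_CLASS_ORDER = ("grassland", "urban", "cropland", "forest", "water", "barren")

# Per-variable defaults: (base level, gradient strength along the SE-NW axis,
# seasonal amplitude, noise sd). Units follow raster.CLIMATE_VARS. The
# seasonal phase peaks in July for the thermal/moisture variables.
_VAR_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "temperature": (2.0, 6.0, 10.0, 1.0),          # degC
    "precipitation": (45.0, 35.0, 40.0, 8.0),      # mm/month
    "relative_humidity": (55.0, 15.0, 10.0, 3.0),  # %
    "soil_temperature": (4.0, 5.0, 8.0, 1.0),      # degC
    "soil_moisture": (0.20, 0.10, 0.05, 0.02),     # fraction
    "solar_radiation": (550.0, 60.0, 180.0, 25.0), # MJ m-2 month-1
}

_PHYS_RANGE = {
    "precipitation": (0.0, None),
    "relative_humidity": (0.0, 100.0),
    "soil_moisture": (0.0, 1.0),
    "solar_radiation": (0.0, None),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic study domain.

    ``gradient_strength`` is the expected difference between the southeast
    and northwest corners of the domain; positive values put the high end
    in the southeast, as over the study region.
    """

    grid_rows: int = 64
    grid_cols: int = 64
    pixel_size_deg: float = 0.011305581
    origin_lon: float = 85.0
    origin_lat: float = 35.0
    start_year: int = 2025
    end_year: int = 2026
    correlation_length: float = 6.0
    gradient_strength: dict[str, float] = field(default_factory=dict)
    seasonal_amplitude: dict[str, float] = field(default_factory=dict)
    seasonal_phase: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    class_proportions: tuple[float, ...] = (0.62, 0.001, 0.027, 0.11, 0.017, 0.225)
    change_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.pixel_size_deg <= 0:
            raise ValueError("pixel_size_deg must be positive")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if len(self.class_proportions) != 6:
            raise ValueError("class_proportions needs six entries")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be nonnegative")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.change_rate <= 1.0:
            raise ValueError("change_rate must be in [0, 1]")

    def var_params(self, name: str) -> tuple[float, float, float, float, float]:
        """(base, gradient, amplitude, phase, noise_sd) for one variable."""
        base, grad, amp, sd = _VAR_DEFAULTS[name]
        return (
            base,
            self.gradient_strength.get(name, grad),
            self.seasonal_amplitude.get(name, amp),
            self.seasonal_phase.get(name, 7.0),  # peak month (July)
            self.noise_sd.get(name, sd),
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["class_proportions"] = list(self.class_proportions)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        d = yaml.safe_load(text)
        if "class_proportions" in d:
            d["class_proportions"] = tuple(d["class_proportions"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruthLink:
    """The NDVI-generating function.

    NDVI = clip(lo + (hi - lo) * sigmoid(eta), lo, hi) + noise, where
    eta = intercept + sum_v coef[v] * z_v + seasonal * cos(2*pi*(month-7)/12)
    and z_v are the climate drivers standardized by the fixed scales below.
    The logistic keeps the link monotone in every driver and bounded; the
    final clip enforces the physical range after noise.
    """

    intercept: float = 0.0
    coefs: dict[str, float] = field(default_factory=lambda: {
        "temperature": 0.9,
        "precipitation": 0.9,
        "relative_humidity": 0.25,
        "soil_temperature": 0.35,
        "soil_moisture": 0.3,
    })
    seasonal: float = 0.5
    ndvi_noise_sd: float = 0.02
    ndvi_lo: float = -0.2
    ndvi_hi: float = 0.95

    def __post_init__(self) -> None:
        if not self.ndvi_lo < self.ndvi_hi:
            raise ValueError("ndvi_lo must be < ndvi_hi")
        if self.ndvi_noise_sd < 0:
            raise ValueError("ndvi_noise_sd must be nonnegative")

    # fixed standardization scales (center, spread) per driver
    SCALES = {
        "temperature": (5.0, 8.0),
        "precipitation": (60.0, 40.0),
        "relative_humidity": (60.0, 15.0),
        "soil_temperature": (6.0, 7.0),
        "soil_moisture": (0.25, 0.08),
    }

    def eta(self, climate_values: dict[str, np.ndarray], month: int) -> np.ndarray:
        z = self.intercept + self.seasonal * np.cos(2 * np.pi * (month - 7) / 12.0)
        for name, c in self.coefs.items():
            mu, sd = self.SCALES[name]
            z = z + c * (climate_values[name] - mu) / sd
        return z

    def mean_ndvi(self, climate_values: dict[str, np.ndarray], month: int) -> np.ndarray:
        s = 1.0 / (1.0 + np.exp(-self.eta(climate_values, month)))
        return self.ndvi_lo + (self.ndvi_hi - self.ndvi_lo) * s

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruthLink":
        return cls(**yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------

def make_gaussian_field(rows: int, cols: int, correlation_length: float,
                        seed: int) -> np.ndarray:
    """Zero-mean, unit-variance spatially autocorrelated field.

    Gaussian-kernel convolution (via FFT on a padded domain, so the field
    is not wrapped) of white noise, renormalized to unit variance in
    expectation. Deterministic given the seed.
    """
    if rows < 8 or cols < 8:
        raise ValueError("rows and cols must be >= 8")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    pad = int(np.ceil(4 * correlation_length))
    pr, pc = rows + 2 * pad, cols + 2 * pad
    white = rng.standard_normal((pr, pc))

    ky = np.fft.fftfreq(pr)
    kx = np.fft.fftfreq(pc)
    KX, KY = np.meshgrid(kx, ky)
    # FT of a Gaussian kernel with sd = correlation_length pixels
    kernel_ft = np.exp(-2 * (np.pi * correlation_length) ** 2 * (KX**2 + KY**2))
    smooth = np.real(np.fft.ifft2(np.fft.fft2(white) * kernel_ft))
    # var of the smoothed field = sum of squared kernel weights
    norm = np.sqrt(np.sum(np.abs(kernel_ft) ** 2) / (pr * pc))
    field = smooth[pad:pad + rows, pad:pad + cols] / norm
    return field


def _sub_seed(seed: int, *tags: object) -> int:
    """Deterministic sub-stream seed from a base seed and tags (< 2**31)."""
    import zlib
    s = ":".join(str(t) for t in tags)
    return (seed * 2654435761 + zlib.crc32(s.encode())) % (2**31 - 1)


def _gradient_surface(rows: int, cols: int) -> np.ndarray:
    """0 at the NW corner, 1 at the SE corner, bilinear in between."""
    r = np.arange(rows) / max(rows - 1, 1)
    c = np.arange(cols) / max(cols - 1, 1)
    C, R = np.meshgrid(c, r)
    return 0.5 * (R + C)  # south = high row index, east = high col index


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def synth_climate(cfg: SyntheticConfig) -> ClimateCube:
    """Generate the six aligned monthly climate stacks.

    Each variable is base + gradient*(SE surface) + seasonal cosine peaked
    at its phase month + a spatially autocorrelated noise field per month,
    clipped to its physical range.
    """
    rows, cols = cfg.grid_rows, cfg.grid_cols
    grad_surface = _gradient_surface(rows, cols)
    months = month_range(cfg.start_year, cfg.end_year)
    stacks: dict[str, MonthStack] = {}
    for name in CLIMATE_VARS:
        base, grad, amp, phase, sd = cfg.var_params(name)
        grids: dict[tuple[int, int], Grid2D] = {}
        # one persistent spatial pattern per variable plus monthly noise
        static = make_gaussian_field(rows, cols, cfg.correlation_length,
                                     _sub_seed(cfg.seed, "climate-static", name))
        for (year, month) in months:
            seasonal = amp * np.cos(2 * np.pi * (month - phase) / 12.0)
            noise = 0.0
            if sd > 0:
                noise = sd * make_gaussian_field(
                    rows, cols, cfg.correlation_length,
                    _sub_seed(cfg.seed, "climate", name, year, month))
            vals = base + grad * grad_surface + seasonal + 0.5 * sd * static + noise
            lo, hi = _PHYS_RANGE.get(name, (None, None))
            if lo is not None or hi is not None:
                vals = np.clip(vals, lo, hi)
            grids[(year, month)] = Grid2D(
                values=vals, origin_lon=cfg.origin_lon, origin_lat=cfg.origin_lat,
                pixel_size=cfg.pixel_size_deg)
        stacks[name] = MonthStack(grids)
    units = {
        "temperature": "degC", "precipitation": "mm month-1",
        "relative_humidity": "%", "soil_temperature": "degC",
        "soil_moisture": "fraction", "solar_radiation": "MJ m-2 month-1",
    }
    return ClimateCube(stacks, units=units)


# ---------------------------------------------------------------------------
# NDVI
# ---------------------------------------------------------------------------

def synth_ndvi(climate: ClimateCube, link: GroundTruthLink, seed: int) -> MonthStack:
    """NDVI from the ground-truth link applied to the climate cube.

    Noise is added inside the final clip, so the output always lies in
    [ndvi_lo, ndvi_hi].
    """
    grids: dict[tuple[int, int], Grid2D] = {}
    for (year, month) in climate.months:
        vals = {name: climate[name][(year, month)].values for name in link.coefs}
        mean = link.mean_ndvi(vals, month)
        if link.ndvi_noise_sd > 0:
            rng = np.random.default_rng(_sub_seed(seed, "ndvi", year, month))
            mean = mean + link.ndvi_noise_sd * rng.standard_normal(mean.shape)
        ndvi = np.clip(mean, link.ndvi_lo, link.ndvi_hi)
        ref = climate.template
        grids[(year, month)] = Grid2D(
            values=ndvi, origin_lon=ref.origin_lon, origin_lat=ref.origin_lat,
            pixel_size=ref.pixel_size)
    return MonthStack(grids)


# ---------------------------------------------------------------------------
# Land use
# ---------------------------------------------------------------------------

#: When a cell changes class, where it preferentially goes (echoes a
#: cropland-retirement narrative: cropland converts mostly to forest and
#: grassland; grassland exchanges with barren).
_TRANSITION_PREF: dict[str, dict[str, float]] = {
    "grassland": {"barren": 0.6, "forest": 0.25, "cropland": 0.1, "water": 0.04, "urban": 0.01},
    "urban": {"grassland": 0.5, "barren": 0.4, "cropland": 0.1},
    "cropland": {"forest": 0.45, "grassland": 0.45, "urban": 0.06, "barren": 0.04},
    "forest": {"grassland": 0.8, "cropland": 0.15, "barren": 0.05},
    "water": {"barren": 0.6, "grassland": 0.35, "urban": 0.05},
    "barren": {"grassland": 0.85, "water": 0.1, "urban": 0.05},
}


def synth_landuse_pair(cfg: SyntheticConfig) -> tuple[LandUseGrid, LandUseGrid]:
    """Two-epoch land-use pair with ~change_rate of cells reassigned.

    The first epoch is drawn i.i.d. from ``class_proportions`` with mild
    spatial clumping (a Gaussian field orders cells so equal-class cells
    cluster); the second epoch reassigns a seeded random subset following
    the fixed transition preferences.
    """
    rows, cols = cfg.grid_rows, cfg.grid_cols
    name_to_code = {v: k for k, v in LANDUSE_CLASSES.items()}
    # spatially clumped class draw: rank a smooth field, then cut by quantiles
    fld = make_gaussian_field(rows, cols, cfg.correlation_length,
                              _sub_seed(cfg.seed, "landuse-base"))
    order = np.argsort(fld, axis=None)
    codes = np.empty(rows * cols, dtype=np.int32)
    edges = np.cumsum(cfg.class_proportions)
    start = 0
    for cls_name, edge in zip(_CLASS_ORDER, edges):
        stop = int(round(edge * rows * cols))
        codes[order[start:stop]] = name_to_code[cls_name]
        start = stop
    codes[order[start:]] = name_to_code[_CLASS_ORDER[-1]]
    lu1 = codes.reshape(rows, cols)

    lu2 = lu1.copy()
    rng = np.random.default_rng(_sub_seed(cfg.seed, "landuse-change"))
    n_change = int(round(cfg.change_rate * rows * cols))
    if n_change > 0:
        idx = rng.choice(rows * cols, size=n_change, replace=False)
        flat = lu2.reshape(-1)
        for i in idx:
            cur = LANDUSE_CLASSES[int(flat[i])]
            prefs = _TRANSITION_PREF[cur]
            names = list(prefs)
            p = np.array([prefs[n] for n in names])
            new = rng.choice(names, p=p / p.sum())
            flat[i] = name_to_code[str(new)]

    def as_lu(arr: np.ndarray) -> LandUseGrid:
        return LandUseGrid(grid=Grid2D(
            values=arr.astype(np.int32), origin_lon=cfg.origin_lon,
            origin_lat=cfg.origin_lat, pixel_size=cfg.pixel_size_deg))

    return as_lu(lu1), as_lu(lu2)
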