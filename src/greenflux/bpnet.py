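"""Backpropagation feed-forward network for monthly NDVI regression.

One sigmoid hidden layer, linear output:

    h_j = sigmoid(sum_i w_ij x_i + b_j)
    y_k = sum_j w_jk h_j + b_k

trained by full-batch gradient descent (optional momentum) on mean squared
error, with min–max normalization of inputs and targets to [0, 1] whose
bounds travel with the parameters. Validation metrics are the sample
Pearson correlation R, R² = R·R (linear-fit convention), MSE, and NRMSE
(RMSE over the observed range, in percent). A Monte-Carlo procedure jitters
each raw input element by a multiplicative ±rho uniform perturbation and
aggregates the prediction mean, per-sample spread, and the MSE distribution
across simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .raster import ClimateCube, Grid2D

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "ValidationReport",
    "MonteCarloReport",
    "forward",
    "train",
    "build_features",
    "predict_ndvi_points",
    "pearson_r",
    "nrmse",
    "monte_carlo",
]

#: Climate drivers fed to the network, in column order.
FEATURE_VARS = ("temperature", "precipitation", "relative_humidity",
                "soil_temperature", "soil_moisture")


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given series (e.g. zero variance)."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NetworkParams:
    """Weights, biases and normalization bounds of the trained network."""

    w_ih: np.ndarray          # (n_in, n_hidden)
    b_h: np.ndarray           # (n_hidden,)
    w_ho: np.ndarray          # (n_hidden, n_out)
    b_o: np.ndarray           # (n_out,)
    x_min: np.ndarray | None = None   # raw-input bounds, (n_in,)
    x_max: np.ndarray | None = None
    y_min: float | None = None        # raw-target bounds
    y_max: float | None = None

    def __post_init__(self) -> None:
        self.w_ih = np.atleast_2d(np.asarray(self.w_ih, dtype=float))
        self.b_h = np.asarray(self.b_h, dtype=float).ravel()
        self.w_ho = np.atleast_2d(np.asarray(self.w_ho, dtype=float))
        self.b_o = np.asarray(self.b_o, dtype=float).ravel()
        n_in, m = self.w_ih.shape
        if self.b_h.shape != (m,):
            raise ValueError("b_h inconsistent with w_ih")
        if self.w_ho.shape[0] != m:
            raise ValueError("w_ho inconsistent with hidden dimension")
        if self.b_o.shape != (self.w_ho.shape[1],):
            raise ValueError("b_o inconsistent with w_ho")
        for arr in (self.w_ih, self.b_h, self.w_ho, self.b_o):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.w_ih.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    @property
    def normalized(self) -> bool:
        return self.x_min is not None

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "w_ih": self.w_ih.tolist(), "b_h": self.b_h.tolist(),
            "w_ho": self.w_ho.tolist(), "b_o": self.b_o.tolist(),
            "x_min": None if self.x_min is None else np.asarray(self.x_min).tolist(),
            "x_max": None if self.x_max is None else np.asarray(self.x_max).tolist(),
            "y_min": self.y_min, "y_max": self.y_max,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkParams":
        d = json.loads(text)
        return cls(
            w_ih=np.array(d["w_ih"]), b_h=np.array(d["b_h"]),
            w_ho=np.array(d["w_ho"]), b_o=np.array(d["b_o"]),
            x_min=None if d["x_min"] is None else np.array(d["x_min"]),
            x_max=None if d["x_max"] is None else np.array(d["x_max"]),
            y_min=d["y_min"], y_max=d["y_max"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class TrainConfig:
    hidden_dim: int = 10
    learning_rate: float = 0.2
    momentum: float = 0.9
    max_epochs: int = 600
    tol: float = 1e-9            # stop when the MSE improvement drops below
    validation_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ValidationReport:
    r: float
    r2: float
    mse: float
    nrmse_pct: float


@dataclass(frozen=True)
class MonteCarloReport:
    rho: float
    n_sims: int
    original_mse: float
    mean_mse: float
    std_mse: float
    mse_per_sim: np.ndarray       # (N,)
    mean_prediction: np.ndarray   # (n_samples,)
    sigma_y: np.ndarray           # (n_samples,)


# ---------------------------------------------------------------------------
# Forward pass and metrics
# ---------------------------------------------------------------------------

def _forward_normalized(params: NetworkParams, xn: np.ndarray) -> np.ndarray:
    h = _sigmoid(xn @ params.w_ih + params.b_h)
    return h @ params.w_ho + params.b_o


def forward(params: NetworkParams, inputs: np.ndarray) -> np.ndarray:
    """Network prediction for one input vector or a batch (rows = samples).

    If normalization bounds are stored, raw inputs are min–max scaled to
    [0, 1] first and the output is mapped back to the raw target scale.
    """
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != params.n_inputs:
        raise ValueError(
            f"expected {params.n_inputs} input features, got {x.shape[1]}")
    if params.normalized:
        span = np.where(params.x_max - params.x_min > 0,
                        params.x_max - params.x_min, 1.0)
        x = (x - params.x_min) / span
    y = _forward_normalized(params, x)
    if params.normalized and params.y_min is not None:
        y = params.y_min + y * (params.y_max - params.y_min)
    if y.shape[1] == 1:
        y = y[:, 0]
    return y[0] if single else y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("correlation undefined for constant series")
    return float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))


def nrmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """RMSE normalized by the observed range, in percent."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("series must have equal length >= 1")
    rng = obs.max() - obs.min()
    if rng == 0:
        raise UndefinedStatisticError("NRMSE undefined for constant observed series")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return 100.0 * rmse / rng


def _mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    return float(np.mean((np.asarray(predicted) - np.asarray(observed)) ** 2))


def validation_report(observed: np.ndarray, predicted: np.ndarray) -> ValidationReport:
    r = pearson_r(observed, predicted)
    return ValidationReport(r=r, r2=r * r, mse=_mse(observed, predicted),
                            nrmse_pct=nrmse(observed, predicted))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _loss_and_grads(w_ih, b_h, w_ho, b_o, xn, yn):
    """MSE loss and its gradients for the 1-hidden-layer net (normalized space)."""
    n = xn.shape[0]
    h = _sigmoid(xn @ w_ih + b_h)
    yhat = h @ w_ho + b_o
    err = yhat - yn                      # (n, n_out)
    loss = float(np.mean(err ** 2))
    # d loss / d yhat = 2 err / (n * n_out)
    g_y = 2.0 * err / err.size
    g_w_ho = h.T @ g_y
    g_b_o = g_y.sum(axis=0)
    g_h = g_y @ w_ho.T * h * (1.0 - h)
    g_w_ih = xn.T @ g_h
    g_b_h = g_h.sum(axis=0)
    return loss, (g_w_ih, g_b_h, g_w_ho, g_b_o)


def train(features: np.ndarray, targets: np.ndarray,
          cfg: TrainConfig = TrainConfig(),
          groups: np.ndarray | None = None,
          ) -> tuple[NetworkParams, ValidationReport, np.ndarray]:
    """Train the network; returns (params, held-out report, loss trace).

    The train/validation split is by whole groups when ``groups`` is given
    (one label per sample, e.g. a month index — a temporal block split);
    otherwise by a seeded sample shuffle. With validation_fraction = 0 the
    report is computed on the training data itself.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("features and targets must be aligned and non-empty")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and targets must be finite")

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    if cfg.validation_fraction > 0:
        if groups is not None:
            uniq = np.unique(np.asarray(groups))
            n_val = max(1, int(round(cfg.validation_fraction * uniq.size)))
            val_groups = rng.permutation(uniq)[:n_val]
            val_mask = np.isin(groups, val_groups)
            if val_mask.all() or not val_mask.any():
                raise ValueError("group split left one side empty")
        else:
            perm = rng.permutation(n)
            n_val = max(1, int(round(cfg.validation_fraction * n)))
            val_mask = np.zeros(n, dtype=bool)
            val_mask[perm[:n_val]] = True
    else:
        val_mask = np.zeros(n, dtype=bool)
    X_tr, y_tr = X[~val_mask], y[~val_mask]
    X_va, y_va = X[val_mask], y[val_mask]

    # min-max normalization fitted on the training block only
    x_min, x_max = X_tr.min(axis=0), X_tr.max(axis=0)
    span = np.where(x_max - x_min > 0, x_max - x_min, 1.0)
    y_min, y_max = float(y_tr.min()), float(y_tr.max())
    y_span = (y_max - y_min) or 1.0
    xn = (X_tr - x_min) / span
    yn = ((y_tr - y_min) / y_span)[:, None]

    n_in, m = X.shape[1], cfg.hidden_dim
    w_ih = rng.uniform(-0.5, 0.5, size=(n_in, m))
    b_h = rng.uniform(-0.5, 0.5, size=m)
    w_ho = rng.uniform(-0.5, 0.5, size=(m, 1))
    b_o = rng.uniform(-0.5, 0.5, size=1)

    vel = [np.zeros_like(p) for p in (w_ih, b_h, w_ho, b_o)]
    trace = np.empty(cfg.max_epochs)
    prev = np.inf
    n_done = 0
    for epoch in range(cfg.max_epochs):
        loss, grads = _loss_and_grads(w_ih, b_h, w_ho, b_o, xn, yn)
        trace[epoch] = loss
        n_done = epoch + 1
        if abs(prev - loss) < cfg.tol and epoch > 0:
            break
        prev = loss
        params_list = [w_ih, b_h, w_ho, b_o]
        for i, (p, g) in enumerate(zip(params_list, grads)):
            vel[i] = cfg.momentum * vel[i] - cfg.learning_rate * g
            p += vel[i]

    params = NetworkParams(w_ih=w_ih, b_h=b_h, w_ho=w_ho, b_o=b_o,
                           x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max)
    X_rep, y_rep = (X_va, y_va) if val_mask.any() else (X_tr, y_tr)
    report = validation_report(y_rep, forward(params, X_rep))
    return params, report, trace[:n_done]


# ---------------------------------------------------------------------------
# Gridded prediction
# ---------------------------------------------------------------------------

def build_features(climate: ClimateCube, month_encoding: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, list]:
    """Flatten a climate cube into a (samples, features) design matrix.

    Returns (X, index, months) where ``index`` holds (month_pos, row, col)
    for every sample and ``months`` the ordered (year, month) keys. With
    ``month_encoding`` two cyclic columns cos/sin(2*pi*month/12) are
    appended.
    """
    months = list(climate.months)
    rows, cols = climate.template.shape
    blocks, idx = [], []
    for t, (year, month) in enumerate(months):
        cols_data = [climate[v][(year, month)].values.ravel() for v in FEATURE_VARS]
        if month_encoding:
            ang = 2 * np.pi * month / 12.0
            cols_data.append(np.full(rows * cols, np.cos(ang)))
            cols_data.append(np.full(rows * cols, np.sin(ang)))
        blocks.append(np.column_stack(cols_data))
        rr, cc = np.unravel_index(np.arange(rows * cols), (rows, cols))
        idx.append(np.column_stack([np.full(rows * cols, t), rr, cc]))
    return np.vstack(blocks), np.vstack(idx), months


def predict_ndvi_points(params: NetworkParams, climate: ClimateCube,
                        sample_fraction: float = 1.0, seed: int = 0,
                        month_encoding: bool = True,
                        clip: tuple[float, float] = (-0.2, 0.95),
                        ) -> dict[tuple[int, int], "SamplePointsLike"]:
    """Predict NDVI at a seeded random subset of pixel centers, per month.

    Returns a mapping (year, month) -> object with ``lon``, ``lat``,
    ``values`` arrays (consumable by the kriging stage). Predictions are
    clipped to the physical NDVI range.
    """
    if not params.normalized:
        raise ValueError("params carry no normalization bounds; train first")
    if not 0.0 < sample_fraction <= 1.0:
        raise ValueError("sample_fraction must be in (0, 1]")
    from .kriging import SamplePoints  # local import to avoid a cycle

    template = climate.template
    LON, LAT = template.pixel_centers()
    lon_flat, lat_flat = LON.ravel(), LAT.ravel()
    n_pix = lon_flat.size
    out: dict[tuple[int, int], SamplePoints] = {}
    for t, (year, month) in enumerate(climate.months):
        rng = np.random.default_rng((seed + 7919 * t) % (2**31 - 1))
        if sample_fraction < 1.0:
            k = max(1, int(round(sample_fraction * n_pix)))
            sel = np.sort(rng.choice(n_pix, size=k, replace=False))
        else:
            sel = np.arange(n_pix)
        feats = [climate[v][(year, month)].values.ravel()[sel] for v in FEATURE_VARS]
        if month_encoding:
            ang = 2 * np.pi * month / 12.0
            feats.append(np.full(sel.size, np.cos(ang)))
            feats.append(np.full(sel.size, np.sin(ang)))
        X = np.column_stack(feats)
        pred = np.clip(np.atleast_1d(forward(params, X)), clip[0], clip[1])
        out[(year, month)] = SamplePoints(
            lon=lon_flat[sel], lat=lat_flat[sel], values=pred)
    return out


SamplePointsLike = "greenflux.kriging.SamplePoints"


# ---------------------------------------------------------------------------
# Monte-Carlo robustness
# ---------------------------------------------------------------------------

def monte_carlo(params: NetworkParams, features: np.ndarray, targets: np.ndarray,
                rho: float = 0.02, n_sims: int = 300, seed: int = 0,
                ) -> MonteCarloReport:
    """Multiplicative input-perturbation robustness analysis.

    Each simulation k perturbs every raw input element as
    p_ij * (1 + rho * (2 r_ij - 1)) with r_ij ~ U(0, 1), runs the trained
    network, and records the MSE against the observed targets. The report
    aggregates the MSE distribution, the per-sample mean prediction and
    the per-sample standard deviation across simulations.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    base_pred = np.atleast_1d(forward(params, X))
    original_mse = _mse(y, base_pred)

    rng = np.random.default_rng(seed)
    preds = np.empty((n_sims, X.shape[0]))
    mse_k = np.empty(n_sims)
    for k in range(n_sims):
        r = rng.uniform(0.0, 1.0, size=X.shape)
        Xk = X * (1.0 + rho * (2.0 * r - 1.0))
        pk = np.atleast_1d(forward(params, Xk))
        preds[k] = pk
        mse_k[k] = _mse(y, pk)
    mean_pred = preds.mean(axis=0)
    if rho == 0.0 or n_sims == 1:
        # all simulations coincide; the spread is exactly zero
        sigma_y = np.zeros(X.shape[0])
        std_mse = 0.0
        mean_pred = base_pred
        mse_k[:] = original_mse
        mean_mse = original_mse
    else:
        sigma_y = preds.std(axis=0, ddof=1)
        std_mse = float(mse_k.std(ddof=1))
        mean_mse = float(mse_k.mean())
    return MonteCarloReport(
        rho=rho, n_sims=n_sims, original_mse=original_mse,
        mean_mse=mean_mse, std_mse=std_mse,
        mse_per_sim=mse_k, mean_prediction=mean_pred, sigma_y=sigma_y)
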