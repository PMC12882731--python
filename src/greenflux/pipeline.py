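"""End-to-end orchestration: synthetic inputs -> trained NDVI network ->
kriged NDVI surfaces -> CASA NPP -> wetland carbon -> land-use transfer
matrix -> climate-NPP correlations, from one config with one global seed.

Every stochastic stage derives its own sub-seed from (global seed, stage
name), so re-running a single stage is independent of execution order.
A :class:`RunManifest` records every produced file with a checksum, the
echoed config, per-stage timings and the seed record; ``validate_run``
re-checks the structural invariants on the files themselves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bpnet, carbon, casa, kriging, stats, synth
from .raster import Grid2D, LandUseGrid, MonthStack, write_landuse, write_raster, read_raster

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_run"]

log = logging.getLogger("greenflux")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31)."""
    return (global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    link: synth.GroundTruthLink = field(default_factory=synth.GroundTruthLink)
    train: bpnet.TrainConfig = field(default_factory=bpnet.TrainConfig)
    casa: casa.CasaParams = field(default_factory=casa.CasaParams)
    sample_fraction: float = 0.05     # pixel fraction kept as discrete points
    n_lags: int = 12
    wetland_classes: tuple[str, ...] = ("water",)
    b_factor: float = carbon.B_WETLAND
    cell_area_km2: float = 1.255 ** 2
    aggregation: str = "pixel-annual"
    seed: int = 0
    out_dir: str = "greenflux_run"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["synthetic"]["class_proportions"] = list(self.synthetic.class_proportions)
        d["wetland_classes"] = list(self.wetland_classes)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        kw = {}
        if "synthetic" in d:
            sd = d.pop("synthetic")
            sd["class_proportions"] = tuple(sd.get("class_proportions",
                                                   synth.SyntheticConfig().class_proportions))
            kw["synthetic"] = synth.SyntheticConfig(**sd)
        if "link" in d:
            kw["link"] = synth.GroundTruthLink(**d.pop("link"))
        if "train" in d:
            kw["train"] = bpnet.TrainConfig(**d.pop("train"))
        if "casa" in d:
            kw["casa"] = casa.CasaParams(**d.pop("casa"))
        if "wetland_classes" in d:
            d["wetland_classes"] = tuple(d["wetland_classes"])
        kw.update(d)
        return cls(**kw)


@dataclass
class RunManifest:
    out_dir: str
    seed: int
    config_yaml: str
    files: dict[str, str] = field(default_factory=dict)     # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    seeds: dict[str, int] = field(default_factory=dict)
    summary: dict[str, float] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path)] = digest

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


class _StageTimer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        log.info("stage %s ...", self.stage)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.timings[self.stage] = time.perf_counter() - self.t0
        if exc_type is not None:
            log.error("stage %s failed: %s", self.stage, exc)
        return False


def run_pipeline(config: PipelineConfig, params_file: str | None = None
                 ) -> RunManifest:
    """Execute every stage and write all outputs under ``config.out_dir``.

    ``params_file`` reuses a serialized network instead of training.
    Identical config + seed give identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out_dir=str(out), seed=config.seed,
                           config_yaml=config.to_yaml())
    log.info("config:\n%s", manifest.config_yaml)
    (out / "config.yaml").write_text(config.to_yaml())
    manifest.record(out / "config.yaml")

    # ---- synthetic inputs -------------------------------------------------
    with _StageTimer(manifest, "synth"):
        s = stage_seed(config.seed, "synth")
        manifest.seeds["synth"] = s
        scfg = dataclasses.replace(config.synthetic, seed=s)
        climate = synth.synth_climate(scfg)
        ndvi_true = synth.synth_ndvi(climate, config.link,
                                     stage_seed(config.seed, "ndvi"))
        lu1, lu2 = synth.synth_landuse_pair(scfg)
        (out / "ground_truth_link.yaml").write_text(config.link.to_yaml())
        manifest.record(out / "ground_truth_link.yaml")
        write_landuse(lu1, out / "landuse_t1.tif")
        write_landuse(lu2, out / "landuse_t2.tif")
        for p in ("landuse_t1.tif", "landuse_t2.tif"):
            manifest.record(out / p)

    # ---- network ----------------------------------------------------------
    with _StageTimer(manifest, "train"):
        X, _, months = bpnet.build_features(climate)
        y = np.concatenate([ndvi_true[k].values.ravel() for k in months])
        groups = np.repeat(np.arange(len(months)),
                           climate.template.values.size)
        if params_file:
            params = bpnet.NetworkParams.load(params_file)
            report = bpnet.validation_report(y, np.atleast_1d(bpnet.forward(params, X)))
        else:
            tseed = stage_seed(config.seed, "train")
            manifest.seeds["train"] = tseed
            tcfg = dataclasses.replace(config.train, seed=tseed)
            params, report, _ = bpnet.train(X, y, tcfg, groups=groups)
        params.save(out / "network_params.json")
        manifest.record(out / "network_params.json")
        pd.DataFrame([dataclasses.asdict(report)]).to_csv(
            out / "validation_metrics.csv", index=False)
        manifest.record(out / "validation_metrics.csv")
        manifest.summary.update(held_out_r=report.r, held_out_nrmse_pct=report.nrmse_pct)

    # ---- Monte-Carlo robustness ------------------------------------------
    with _StageTimer(manifest, "mc"):
        mseed = stage_seed(config.seed, "mc")
        manifest.seeds["mc"] = mseed
        rng = np.random.default_rng(mseed)
        sub = rng.choice(X.shape[0], size=min(2000, X.shape[0]), replace=False)
        mc = bpnet.monte_carlo(params, X[sub], y[sub], rho=0.02, n_sims=300,
                               seed=mseed)
        pd.DataFrame({"mse": mc.mse_per_sim}).to_csv(out / "mc_mse.csv", index=False)
        manifest.record(out / "mc_mse.csv")
        manifest.summary.update(mc_original_mse=mc.original_mse,
                                mc_mean_mse=mc.mean_mse, mc_std_mse=mc.std_mse)

    # ---- predict points + krige ------------------------------------------
    with _StageTimer(manifest, "krige"):
        kseed = stage_seed(config.seed, "krige")
        manifest.seeds["krige"] = kseed
        pts = bpnet.predict_ndvi_points(
            params, climate, sample_fraction=config.sample_fraction, seed=kseed,
            clip=(config.link.ndvi_lo, config.link.ndvi_hi))
        template = climate.template
        ndvi_grids = {}
        for key, sp in pts.items():
            centers, gam, counts = kriging.empirical_semivariogram(
                sp, n_lags=config.n_lags)
            model = kriging.fit_spherical(centers, gam, counts)
            ndvi_grids[key] = kriging.krige_grid(sp, model, template)
        ndvi_stack = MonthStack(ndvi_grids)
        for (yy, mm), g in ndvi_stack.items():
            p = out / f"ndvi_{yy}_{mm:02d}.tif"
            write_raster(g, p)
            manifest.record(p)

    # ---- CASA NPP ---------------------------------------------------------
    with _StageTimer(manifest, "npp"):
        monthly, annual, bounds = casa.npp_from_ndvi(
            ndvi_stack, climate["solar_radiation"], lu2, config.casa,
            temperature=climate["temperature"], moisture=climate["soil_moisture"])
        for yy, g in annual.items():
            p = out / f"npp_annual_{yy}.tif"
            write_raster(g, p)
            manifest.record(p)
        if annual:
            means = {yy: float(g.values.mean()) for yy, g in annual.items()}
            manifest.summary["mean_annual_npp_first_year"] = means[min(means)]
            manifest.summary["mean_annual_npp_last_year"] = means[max(means)]

    # ---- wetland carbon ---------------------------------------------------
    with _StageTimer(manifest, "carbon"):
        mask = carbon.extract_wetland_mask(lu2, config.wetland_classes)
        stats_rows = []
        for yy, g in annual.items():
            cm = carbon.carbon_potential(g, mask, config.b_factor)
            p = out / f"wetland_carbon_{yy}.tif"
            write_raster(cm.grid, p)
            manifest.record(p)
            cmin, cmax, cmean = carbon.summarize_carbon(cm)
            stats_rows.append({"year": yy, "min": cmin, "max": cmax, "mean": cmean})
        pd.DataFrame(stats_rows).to_csv(out / "wetland_carbon_summary.csv", index=False)
        manifest.record(out / "wetland_carbon_summary.csv")

    # ---- land-use accounting ---------------------------------------------
    with _StageTimer(manifest, "landuse"):
        T = carbon.transfer_matrix(lu1, lu2, config.cell_area_km2)
        T.to_csv(out / "transfer_matrix.csv")
        manifest.record(out / "transfer_matrix.csv")
        cs = carbon.change_stats(T)
        cs.to_frame().to_csv(out / "change_stats.csv")
        manifest.record(out / "change_stats.csv")
        summary = carbon.class_npp_stats(annual, lu2)
        summary.yearly_means.to_csv(out / "class_npp_means.csv")
        manifest.record(out / "class_npp_means.csv")

    # ---- correlations -----------------------------------------------------
    with _StageTimer(manifest, "correlate"):
        table = stats.pair_series(climate, annual, config.aggregation)
        corr = stats.correlation_matrix(table)
        corr.to_frame().to_csv(out / "correlation_matrix.csv")
        manifest.record(out / "correlation_matrix.csv")
        manifest.summary["rho_precip_npp"] = corr.value("precipitation", "npp")
        manifest.summary["rho_radiation_npp"] = corr.value("solar_radiation", "npp")

    manifest.save(out / "manifest.json")
    return manifest


def validate_run(manifest: RunManifest) -> list[str]:
    """Re-check invariants on the files a run produced; [] means clean."""
    violations: list[str] = []
    out = Path(manifest.out_dir)
    for fname, digest in manifest.files.items():
        p = Path(fname)
        if not p.exists():
            violations.append(f"missing output: {fname}")
            continue
        if hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            violations.append(f"checksum mismatch: {fname}")
    for p in sorted(out.glob("npp_annual_*.tif")):
        g = read_raster(p)
        if np.any(g.valid_values() < 0):
            violations.append(f"negative NPP in {p.name}")
    tm = out / "transfer_matrix.csv"
    if tm.exists():
        try:
            T = carbon.TransferMatrix.from_csv(tm)
            cs_file = out / "change_stats.csv"
            if cs_file.exists():
                df = pd.read_csv(cs_file, index_col=0)
                if not np.allclose(df["t1_area_km2"].to_numpy(), T.t1_totals(),
                                   rtol=1e-9, atol=1e-6):
                    violations.append("transfer matrix row sums != t1 totals")
                if not np.allclose(df["t2_area_km2"].to_numpy(), T.t2_totals(),
                                   rtol=1e-9, atol=1e-6):
                    violations.append("transfer matrix column sums != t2 totals")
        except Exception as exc:
            violations.append(f"unreadable transfer matrix: {exc}")
    return violations
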