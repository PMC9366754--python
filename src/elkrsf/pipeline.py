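"""End-to-end orchestration of the analysis stages.

Stages: simulate (optional) -> home ranges -> design tables -> RSF fits ->
cross-validation -> trade-off metrics -> NCE models.  Every stage logs
its seed, writes its outputs under the run directory, and records input
checksums in a manifest so a rerun with the same config is verifiably
identical for the deterministic stages.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, homerange, telemetry, tradeoff, validation
from .config import PipelineConfig
from .inference import RSFModelSpec, fit_hierarchical_rsf
from .raster import read_ascii_grid, write_ascii_grid
from .synthetic import simulate_demography, simulate_study

__all__ = ["run_pipeline", "checksum"]

logger = logging.getLogger("elkrsf.pipeline")


def checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _spec_from_config(cfg: PipelineConfig) -> RSFModelSpec:
    return RSFModelSpec(
        fixed_prior_scale=cfg.fixed_prior_scale,
        intercept_ranef_scale=cfg.intercept_ranef_scale,
        slope_sd_upper=cfg.slope_sd_upper,
    )


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the configured stages; returns the run directory.

    With no input paths configured, a synthetic study is generated first
    and analysed exactly like field data would be.
    """
    cfg = PipelineConfig.from_dict(cfg.to_dict())  # never mutate the caller's config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "started": dt.datetime.now().isoformat(timespec="seconds"),
        "seed": cfg.seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    status = {"state": "running"}
    (outdir / "status.json").write_text(json.dumps(status))
    all_stages = ["simulate", "homerange", "design", "fit", "validate", "tradeoff", "nce"]
    stages = stages or all_stages
    try:
        _run_stages(cfg, outdir, manifest, stages)
        status["state"] = "complete"
    except Exception as exc:  # partial outputs stay on disk for inspection
        status["state"] = "failed"
        status["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["finished"] = dt.datetime.now().isoformat(timespec="seconds")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "status.json").write_text(json.dumps(status))
        logger.removeHandler(handler)
        handler.close()
    return outdir


def _require(path: str | None, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise FileNotFoundError(f"missing input for {what}: {path!r}")
    return Path(path)


def _run_stages(cfg: PipelineConfig, outdir: Path, manifest: dict, stages) -> None:
    seed = cfg.seed
    spec = _spec_from_config(cfg)

    if "simulate" in stages and cfg.telemetry_path is None:
        logger.info("simulate: %d individuals, seed %d", cfg.n_individuals, seed)
        study = simulate_study(
            n_individuals=cfg.n_individuals, n_fixes=cfg.n_fixes,
            shape=tuple(cfg.raster_shape), cell_size=cfg.cell_size,
            smoothness=cfg.smoothness, hr_radius=cfg.hr_radius,
            sigma=cfg.sigma, seed=seed,
        )
        write_ascii_grid(study.de, outdir / "de.asc")
        write_ascii_grid(study.lion, outdir / "lion.asc")
        write_ascii_grid(study.wolf, outdir / "wolf.asc")
        telemetry.write_telemetry(study.telemetry, outdir / "telemetry.csv")
        study.truth.to_json(outdir / "truth.json")
        cfg.telemetry_path = str(outdir / "telemetry.csv")
        cfg.de_path = str(outdir / "de.asc")
        cfg.lion_path = str(outdir / "lion.asc")
        cfg.wolf_path = str(outdir / "wolf.asc")
        manifest["stages"]["simulate"] = {"seed": seed}

    telem = telemetry.read_telemetry(_require(cfg.telemetry_path, "telemetry"))
    de = read_ascii_grid(_require(cfg.de_path, "digestible energy raster"))
    lion = read_ascii_grid(_require(cfg.lion_path, "lion raster"))
    wolf = read_ascii_grid(_require(cfg.wolf_path, "wolf raster"))
    for key in ("telemetry_path", "de_path", "lion_path", "wolf_path"):
        manifest["inputs"][key] = checksum(Path(getattr(cfg, key)))

    hrs: dict = {}
    pop_hr = None
    if "homerange" in stages:
        logger.info("homerange: %d%% isopleths at %.0f m",
                    round(cfg.isopleth_level * 100), cfg.grid_resolution)
        daily = telemetry.subsample_daily(telem)
        for ind, grp in daily.groupby("animal_id"):
            hr = homerange.estimate_home_range(
                grp, level=cfg.isopleth_level, grid_resolution=cfg.grid_resolution,
                owner=str(ind),
            )
            hrs[str(ind)] = homerange.clip_home_range(hr, de.extent)
        pop_hr = homerange.clip_home_range(
            homerange.estimate_home_range(
                daily, level=cfg.isopleth_level, grid_resolution=cfg.grid_resolution
            ),
            de.extent,
        )
        wkt = {k: v.to_wkt() for k, v in hrs.items()}
        wkt["population"] = pop_hr.to_wkt()
        (outdir / "home_ranges.wkt.json").write_text(json.dumps(wkt))
        manifest["stages"]["homerange"] = {"n_individuals": len(hrs)}

    tables: dict[str, pd.DataFrame] = {}
    constants: dict = {}
    if "design" in stages:
        logger.info("design: second order %d/%d, third order 1:%d, seed %d",
                    cfg.n_used_second, cfg.n_avail_second, cfg.third_order_ratio, seed)
        t2, c2 = design.build_second_order_table(
            hrs, pop_hr, de, lion, wolf,
            n_used=cfg.n_used_second, n_avail=cfg.n_avail_second, seed=seed + 1,
        )
        season = (
            tuple(int(v) for v in cfg.season_start.split("-")),
            tuple(int(v) for v in cfg.season_end.split("-")),
        )
        rest = (
            dt.time(*[int(v) for v in cfg.rest_start.split(":")]),
            dt.time(*[int(v) for v in cfg.rest_end.split(":")]),
        )
        foraging = telemetry.filter_foraging_locations(telem, season=season, rest_window=rest)
        t3, c3 = design.build_third_order_table(
            foraging, hrs, de, lion, wolf, ratio=cfg.third_order_ratio, seed=seed + 2,
        )
        design.write_table(t2, c2, outdir / "table_second.csv", seed=seed + 1)
        design.write_table(t3, c3, outdir / "table_third.csv", seed=seed + 2)
        tables = {"second": t2, "third": t3}
        constants = {"second": c2, "third": c3}
        manifest["stages"]["design"] = {
            "seed_second": seed + 1, "seed_third": seed + 2,
            "rows_second": len(t2), "rows_third": len(t3),
        }

    posteriors: dict = {}
    if "fit" in stages:
        for order, table in tables.items():
            logger.info("fit: %s order, method %s", order, cfg.method)
            post = fit_hierarchical_rsf(
                table, spec, method=cfg.method, draws=cfg.draws, seed=seed + 3,
                mcmc_walkers=cfg.mcmc_walkers, mcmc_warmup=cfg.mcmc_warmup,
                mcmc_steps=cfg.mcmc_steps,
            )
            posteriors[order] = post
            summ = post.summary()
            summ.to_csv(outdir / f"rsf_{order}_summary.csv")
            (outdir / f"rsf_{order}_summary.json").write_text(
                json.dumps({k: {c: float(v) for c, v in r.items()}
                            for k, r in summ.iterrows()}, indent=2)
            )
            post.individual_coefficients().to_csv(outdir / f"rsf_{order}_individual.csv")
        manifest["stages"]["fit"] = {"seed": seed + 3, "method": cfg.method}

    if "validate" in stages:
        reports = {}
        for order, table in tables.items():
            reports[order] = validation.boyce_cross_validate(
                table, spec, n_bins=cfg.cv_bins, k=cfg.cv_folds, seed=seed + 4,
            )
        (outdir / "cv_report.json").write_text(json.dumps(reports, indent=2))
        manifest["stages"]["validate"] = {
            "seed": seed + 4,
            "mean_r_s": {k: v["mean_r_s"] for k, v in reports.items()},
        }

    deltas: dict = {}
    if "tradeoff" in stages and "third" in posteriors:
        t3 = tables["third"]
        for predator in ("ml", "wf"):
            deltas[predator] = tradeoff.compute_tradeoff(
                posteriors["third"], t3, predator=predator,
                de_q=cfg.de_quantile, hi_q=cfg.risk_hi_quantile, lo_q=cfg.risk_lo_quantile,
            )
        pd.DataFrame(deltas).to_csv(outdir / "tradeoffs.csv")
        manifest["stages"]["tradeoff"] = {
            "quantiles": [cfg.de_quantile, cfg.risk_hi_quantile, cfg.risk_lo_quantile]
        }

    if "nce" in stages and deltas:
        if cfg.demography_path is not None:
            demo = pd.read_csv(cfg.demography_path, dtype={"individual_id": str})
            manifest["inputs"]["demography_path"] = checksum(Path(cfg.demography_path))
        else:
            demo = simulate_demography(deltas["ml"], seed=seed + 5)
            demo["tradeoff_wf"] = deltas["wf"].reindex(demo["individual_id"]).to_numpy()
        nce_out = {}
        for predator in ("ml", "wf"):
            if f"tradeoff_{predator}" not in demo.columns:
                data = demo.merge(
                    deltas[predator].rename(f"tradeoff_{predator}"),
                    left_on="individual_id", right_index=True,
                )
            else:
                data = demo
            bf = tradeoff.fit_bodyfat_model(data, predator=predator, seed=seed + 6)
            pg = tradeoff.fit_pregnancy_model(data, predator=predator, seed=seed + 7)
            nce_out[f"bodyfat_{predator}"] = bf.to_dict()
            nce_out[f"pregnancy_{predator}"] = pg.to_dict()
        (outdir / "nce_summaries.json").write_text(json.dumps(nce_out, indent=2))
        manifest["stages"]["nce"] = {"seed": seed + 6, "n_animals": len(demo)}

    for p in sorted(outdir.iterdir()):
        if p.suffix in {".csv", ".json", ".asc"} and p.name not in {
            "manifest.json", "status.json",
        }:
            manifest["outputs"][p.name] = checksum(p)
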