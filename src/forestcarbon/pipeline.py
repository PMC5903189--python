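"""End-to-end pipeline: simulate → estimate → model → report, with manifest.

Each run writes a manifest (seed, config snapshot, file paths, stage
timings, package version) so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allometry import AllometryConfig, estimate_carbon
from .factors import DEFAULT_OUTLIER_THRESHOLD, fit_factor_model
from .report import ci_plot, community_share_pct, descriptive_table, qq_plot
from .simulate import SimulationConfig, write_simulated_inputs

log = logging.getLogger("forestcarbon")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Nested configuration for a full run."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    allometry: AllometryConfig = dataclasses.field(default_factory=AllometryConfig)
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
    two_sided_outliers: bool = False


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config with ``simulation``/``allometry``/``model`` sections.

    Missing sections or keys fall back to the shipped defaults.
    """
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in (raw.get("simulation") or {}).items()
    })
    allo = AllometryConfig(**(raw.get("allometry") or {}))
    model = raw.get("model") or {}
    return PipelineConfig(
        simulation=sim,
        allometry=allo,
        outlier_threshold=float(model.get("outlier_threshold", DEFAULT_OUTLIER_THRESHOLD)),
        two_sided_outliers=bool(model.get("two_sided_outliers", False)),
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                log.error("stage %s: failed: %s", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out, time.perf_counter() - t0

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, seed: int, outdir: Path) -> dict[str, Path]:
    return write_simulated_inputs(outdir, cfg.simulation, seed)


@_stage("estimate")
def _run_estimate(cfg: PipelineConfig, paths: dict[str, Path], outdir: Path) -> Path:
    trees = pd.read_csv(paths["trees"])
    species = pd.read_csv(paths["species"])
    covariates = pd.read_csv(paths["plots"])
    covariates = covariates.loc[covariates["analysed"]].drop(
        columns=["on_forest_land", "analysed"]
    )
    subplots = estimate_carbon(trees, species, covariates, cfg.allometry)
    out = outdir / "subplots.csv"
    subplots.to_csv(out, index=False)
    return out


@_stage("model")
def _run_model(cfg: PipelineConfig, subplots_path: Path, outdir: Path) -> dict[str, Path]:
    subplots = pd.read_csv(subplots_path)
    analysis = fit_factor_model(
        subplots,
        outlier_threshold=cfg.outlier_threshold,
        two_sided_outliers=cfg.two_sided_outliers,
    )
    paths = {
        "coefficients": outdir / "coefficients.csv",
        "contrasts": outdir / "contrasts.csv",
        "qq": outdir / "qq_residuals.png",
        "ci_main": outdir / "ci_stand_factors.png",
        "ci_site": outdir / "ci_site_factors.png",
    }
    analysis.coefficients.to_csv(paths["coefficients"], index=False)
    analysis.contrast_table.to_csv(paths["contrasts"], index=False)
    qq_plot(analysis.final_fit.resid, paths["qq"])
    stand = [f for f in ("stem_volume", "dbh", "tree_count") if f in analysis.contrasts]
    site = [f for f in ("altitude", "region", "ownership") if f in analysis.contrasts]
    if stand:
        ci_plot(analysis, stand, paths["ci_main"])
    if site:
        ci_plot(analysis, site, paths["ci_site"])
    summary = {
        "n_input": int(analysis.first_fit.nobs),
        "n_removed": int(analysis.n_removed),
        "n_analysed": int(analysis.final_fit.nobs),
        "adjusted_r2_first": analysis.first_fit.rsquared_adj,
        "adjusted_r2_final": analysis.final_fit.rsquared_adj,
        "overall_mean_carbon_tC_ha": analysis.overall_mean,
    }
    with open(outdir / "model_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["summary"] = outdir / "model_summary.json"
    return paths


@_stage("report")
def _run_report(subplots_path: Path, outdir: Path) -> Path:
    subplots = pd.read_csv(subplots_path)
    table = descriptive_table(subplots)
    out = outdir / "descriptives.csv"
    table.to_csv(out, index=False)
    share = community_share_pct(subplots) if "ownership" in subplots.columns else None
    with open(outdir / "descriptives_notes.json", "w") as fh:
        json.dump({"community_share_pct": share, "n_subplots": len(subplots)}, fh)
    return out


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | Path = "results",
) -> dict:
    """Run all stages and write ``manifest.json``; returns the manifest."""
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    inputs, timings["simulate"] = _run_simulate(cfg, seed, outdir)
    subplots_path, timings["estimate"] = _run_estimate(cfg, inputs, outdir)
    model_paths, timings["model"] = _run_model(cfg, subplots_path, outdir)
    report_path, timings["report"] = _run_report(subplots_path, outdir)
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": {
            "simulation": dataclasses.asdict(cfg.simulation),
            "allometry": dataclasses.asdict(cfg.allometry),
            "model": {
                "outlier_threshold": cfg.outlier_threshold,
                "two_sided_outliers": cfg.two_sided_outliers,
            },
        },
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {
            "subplots": str(subplots_path),
            **{k: str(v) for k, v in model_paths.items()},
            "descriptives": str(report_path),
        },
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
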