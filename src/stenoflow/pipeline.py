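"""End-to-end orchestration: generate → simulate → datasets → train ×4 → evaluate.

A run is configured by a :class:`PipelineConfig` (profile sizes plus oracle
and network settings), produces the four trained networks — {preoperative,
postoperative} × {velocity, pressure} — and writes an error report, the
stenotic-slab consistency analyses and a JSON manifest from which the run
can be reproduced.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeometryRanges, PROFILES, RunProfile
from .datasets import (DatasetBundle, TARGETS, build_paired_bundles, save_bundle)
from .evaluation import build_error_report, consistency
from .flow_oracle import FluidProperties, InflowSpec
from .network import NetworkConfig, SurrogateModel, build_network, predict_bundle, train

log = logging.getLogger("stenoflow")

__all__ = ["PipelineConfig", "run_pipeline", "report", "run_study"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    profile: str = "smoke"
    seed: int = 0
    out_dir: str | None = None
    ranges: GeometryRanges = field(default_factory=GeometryRanges)
    inflow: InflowSpec = field(default_factory=InflowSpec)
    props: FluidProperties = field(default_factory=FluidProperties)
    loss_coefficient: float = 1.0
    learning_rate: float = 1e-3
    save_bundles: bool = False
    overrides: dict = field(default_factory=dict)  # RunProfile field overrides

    def resolved_profile(self) -> RunProfile:
        base = PROFILES[self.profile]
        if self.overrides:
            from dataclasses import replace
            base = replace(base, **self.overrides)
        return base


def _network_config(target: str, profile: RunProfile, seed: int,
                    lr: float) -> NetworkConfig:
    return NetworkConfig(
        output_dim=3 if target == "velocity" else 1,
        learning_rate=lr,
        epochs=profile.epochs,
        seed=seed,
        cavity_subsample=profile.cavity_subsample,
        fluid_subsample=profile.fluid_subsample,
        eval_subsample=profile.eval_subsample,
    )


def run_study(config: PipelineConfig) -> dict:
    """Run the full study in memory; returns bundles, models, reports, metrics."""
    profile = config.resolved_profile()
    t0 = time.time()
    log.info("generating %d models (profile %s, seed %d)",
             profile.n_models, profile.name, config.seed)
    bundles = build_paired_bundles(
        profile.n_models, config.seed, ranges=config.ranges,
        n_cavity=profile.n_cavity, n_fluid=profile.n_fluid,
        inflow=config.inflow, props=config.props,
        loss_coefficient=config.loss_coefficient)
    log.info("generation done in %.1f s", time.time() - t0)

    models: dict[tuple[str, str], SurrogateModel] = {}
    histories = {}
    predictions = {}
    report_frames = []
    consistency_results = {}
    combo_ids = {("preoperative", "velocity"): 0, ("preoperative", "pressure"): 1,
                 ("postoperative", "velocity"): 2, ("postoperative", "pressure"): 3}
    for (stage, target), bundle in bundles.items():
        net_seed = int(np.random.SeedSequence(
            [config.seed, combo_ids[(stage, target)]]).generate_state(1)[0]
            % (2 ** 31))
        cfg = _network_config(target, profile, net_seed, config.learning_rate)
        model = build_network(cfg)
        t1 = time.time()
        model, hist = train(model, bundle, cfg)
        log.info("trained %s/%s: %d epochs in %.1f s (best val %.3e @ epoch %d)",
                 stage, target, cfg.epochs, time.time() - t1,
                 hist.best_val_loss, hist.best_epoch)
        preds = predict_bundle(model, bundle, "test")
        models[(stage, target)] = model
        histories[(stage, target)] = hist
        predictions[(stage, target)] = preds
        rep = build_error_report(bundle, preds, "test")
        report_frames.append(rep.table)
        if target == "velocity":
            consistency_results[stage] = consistency(bundle, preds, "test")

    table = pd.concat(report_frames, ignore_index=True)
    metrics = summarize_metrics(table, consistency_results)
    return {
        "bundles": bundles, "models": models, "histories": histories,
        "predictions": predictions, "report_table": table,
        "consistency": consistency_results, "metrics": metrics,
        "profile": profile, "elapsed_s": time.time() - t0,
    }


def summarize_metrics(table: pd.DataFrame, consistency_results: dict) -> dict:
    """Headline numbers: worst regional MRE, worst whole-model NMAE, Pearson r."""
    whole = table[table["region"] == "whole"]
    metrics = {
        "max_region_mre_pct": float(table["mre_mean"].max()),
        "max_whole_model_nmae_pct": float(whole["nmae_mean"].max()),
    }
    for stage, res in consistency_results.items():
        key = "pre" if stage == "preoperative" else "post"
        metrics[f"consistency_r_{key}"] = res.r
        metrics[f"consistency_p_{key}"] = res.p_value
    return metrics


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the study and persist models, reports and a reproducibility manifest."""
    if config.out_dir is None:
        raise ValueError("run_pipeline needs an output directory")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_study(config)
    profile = result["profile"]
    artifacts: dict[str, str] = {}

    for (stage, target), model in result["models"].items():
        name = f"model_{stage}_{target}.npz"
        model.save(out / name)
        artifacts[f"model/{stage}/{target}"] = name
    result["report_table"].to_csv(out / "error_report.csv", index=False)
    artifacts["error_report"] = "error_report.csv"
    for stage, res in result["consistency"].items():
        name = f"consistency_{stage}.csv"
        res.scatter_frame().to_csv(out / name, index=False)
        artifacts[f"consistency/{stage}"] = name
    if config.save_bundles:
        for (stage, target), bundle in result["bundles"].items():
            name = f"bundle_{stage}_{target}.h5"
            save_bundle(bundle, out / name)
            artifacts[f"bundle/{stage}/{target}"] = name

    some_bundle = next(iter(result["bundles"].values()))
    manifest = {
        "profile": profile.name,
        "seed": config.seed,
        "n_models": profile.n_models,
        "n_cavity": profile.n_cavity,
        "n_fluid": profile.n_fluid,
        "epochs": profile.epochs,
        "split_sizes": {"train": int(len(some_bundle.train_indices)),
                        "test": int(len(some_bundle.test_indices))},
        "ranges": config.ranges.to_dict(),
        "inflow": {"mass_flow_inlet": config.inflow.mass_flow_inlet,
                   "outlet_reference_pressure": config.inflow.outlet_reference_pressure},
        "fluid_properties": {"density": config.props.density,
                             "viscosity": config.props.viscosity},
        "loss_coefficient": config.loss_coefficient,
        "metrics": result["metrics"],
        "artifacts": artifacts,
        "elapsed_s": result["elapsed_s"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    result["manifest"] = manifest
    return result


def report(run_dir) -> str:
    """Human-readable summary of a finished run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        return f"no runs found under {run_dir}"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    m = manifest["metrics"]
    lines = [
        f"run profile: {manifest['profile']} (seed {manifest['seed']})",
        f"models: {manifest['n_models']} "
        f"({manifest['split_sizes']['train']} train / {manifest['split_sizes']['test']} test)",
        f"max regional MRE: {m['max_region_mre_pct']:.2f}%",
        f"max whole-model NMAE: {m['max_whole_model_nmae_pct']:.2f}%",
    ]
    for key in ("pre", "post"):
        if f"consistency_r_{key}" in m:
            lines.append(
                f"stenotic-slab velocity consistency ({key}): "
                f"r = {m[f'consistency_r_{key}']:.4f}, p = {m[f'consistency_p_{key}']:.2e}")
    return "\n".join(lines)
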