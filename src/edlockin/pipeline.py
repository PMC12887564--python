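"""End-to-end pipeline: simulate → snapshot → train → lock-in → report.

Configuration is one YAML document with ``generator``, ``grid``, ``model``,
``evaluation`` and ``report`` sections; every random stage requires an
explicit seed (absent seeds are rejected up front rather than silently
defaulting).  Re-running the same configuration reproduces every CSV
byte-identically; a manifest records the config hash, seeds and per-stage
row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import ConfigurationError, GeneratorConfig, generate_cohort, write_cohort
from .lockin import LockInEvaluation
from .model import AdmissionModel, HyperParams, split_by_visit
from .report import render_report
from .snapshots import FeatureSchema, make_time_grid, snapshot_matrix

__all__ = ["PipelineConfig", "run_pipeline", "default_config_dict"]

log = logging.getLogger("edlockin")


def default_config_dict(n_visits: int = 2000, seed: int = 0) -> dict:
    """A complete, explicit pipeline configuration (all seeds spelled out)."""
    return {
        "generator": {"n_visits": n_visits, "seed": seed},
        "grid": {"step_minutes": 10, "horizon_minutes": 180},
        "model": {
            "hyperparams": HyperParams().to_dict(),
            "train_fraction": 0.8,
            "split_seed": seed + 1,
        },
        "evaluation": {"threshold": 0.5},
        "report": {"figure_format": "png", "figures": True},
    }


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    generator: GeneratorConfig
    grid_step: int
    grid_horizon: int
    hyperparams: HyperParams
    train_fraction: float
    split_seed: int
    threshold: float
    figure_format: str = "png"
    figures: bool = True
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for section in ("generator", "grid", "model", "evaluation"):
            if section not in d:
                raise ConfigurationError(section, "missing configuration section")
        gen = GeneratorConfig.from_dict(d["generator"])  # validates its seed
        model = d["model"]
        if "split_seed" not in model:
            raise ConfigurationError(
                "model.split_seed", "an explicit split seed is required")
        hp_dict = dict(model.get("hyperparams", {}))
        if hp_dict and "seed" not in hp_dict:
            # the model seed defaults to the split seed, but must be explicit
            # once any hyperparameter is overridden
            hp_dict["seed"] = int(model["split_seed"])
        hp = HyperParams(**hp_dict) if hp_dict else HyperParams(seed=int(model["split_seed"]))
        report = d.get("report", {})
        return cls(
            generator=gen,
            grid_step=int(d["grid"].get("step_minutes", 10)),
            grid_horizon=int(d["grid"].get("horizon_minutes", 180)),
            hyperparams=hp,
            train_fraction=float(model.get("train_fraction", 0.8)),
            split_seed=int(model["split_seed"]),
            threshold=float(d["evaluation"].get("threshold", 0.5)),
            figure_format=str(report.get("figure_format", "png")),
            figures=bool(report.get("figures", True)),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "pipeline.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages and write artifacts + manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": {"generator": config.generator.seed,
                  "split": config.split_seed,
                  "model": config.hyperparams.seed},
        "stages": {},
    }
    t0 = time.time()

    def stage(name):
        log.info("stage %s: start", name)

    try:
        stage("simulate")
        visits, events = generate_cohort(config.generator)
        write_cohort(visits, events, out)
        manifest["stages"]["simulate"] = {
            "n_visits": int(len(visits)), "n_events": int(len(events))}

        stage("snapshot")
        grid = make_time_grid(config.grid_step, config.grid_horizon)
        schema = FeatureSchema()
        snaps = snapshot_matrix(visits, events, grid, schema)
        snaps.to_csv(out / "snapshots.csv", index=False, encoding="utf-8")
        (out / "schema.json").write_text(schema.to_json())
        manifest["stages"]["snapshot"] = {
            "n_rows": int(len(snaps)), "n_features": len(schema.feature_names)}

        stage("train")
        train_ids, test_ids = split_by_visit(
            visits["visit_id"], config.train_fraction, config.split_seed)
        train_snaps = snaps[snaps["visit_id"].isin(train_ids)]
        results = AdmissionModel(train_snaps, schema, config.hyperparams).fit()
        results.save(out / "model.json")
        manifest["stages"]["train"] = {
            "n_train_visits": len(train_ids), "n_test_visits": len(test_ids)}

        stage("evaluate")
        test_snaps = snaps[snaps["visit_id"].isin(test_ids)]
        lock = LockInEvaluation(
            results, test_snaps, visits, grid, config.threshold).run()
        manifest["stages"]["evaluate"] = {
            "n_evaluated": int(lock.confusion.n)}

        stage("report")
        artifacts = render_report(
            lock, out, figure_format=config.figure_format,
            figures=config.figures)
        manifest["stages"]["report"] = {
            "n_artifacts": len(artifacts)}
    except Exception as exc:
        failed = len(manifest["stages"])
        names = ["simulate", "snapshot", "train", "evaluate", "report"]
        manifest["failed_stage"] = names[min(failed, len(names) - 1)]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("stage %s failed: %s", manifest["failed_stage"], exc)
        raise RuntimeError(
            f"pipeline stage {manifest['failed_stage']!r} failed: {exc}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return out
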