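"""End-to-end pipeline: generate -> filter -> train -> encode -> benchmark
-> latent analysis -> fog simulation, with one global seed and a run manifest.

Per-stage seeds derive from the global seed by fixed offsets so each stage
is independently reproducible; the manifest records package version, seeds,
the defaults actually used, and content hashes of the written artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .autoencoder import (
    TrainConfig,
    encode_dataset,
    save_model,
    train_autoencoder,
)
from .classification import (
    FeatureMatrix,
    default_specs,
    evaluate_suite,
    reports_to_table,
    train_classifier,
)
from .errors import StageError
from .fogsim import (
    FogTopology,
    Workload,
    compare_architectures,
    default_topology,
    default_workload,
)
from .latent_analysis import class_average_images, importance_map, save_matrix
from .preprocessing import FilterConfig, preprocess_dataset
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

# Fixed per-stage seed offsets from the global seed.
SEED_OFFSETS = {
    "generate": 0,
    "train_autoencoder": 1,
    "classifier": 2,
    "split": 3,
    "fog_workload": 4,
}


@dataclass
class PipelineConfig:
    """Everything needed to rerun the full pipeline from scratch."""

    out_dir: str = "fogbci_run"
    seed: int = 0
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    topology: FogTopology = field(default_factory=default_topology)
    workload: Workload = field(default_factory=default_workload)
    filter_signal: bool = True
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw: dict = {}
        for key in ("out_dir", "seed", "filter_signal", "log_level"):
            if key in raw:
                kw[key] = raw[key]
        if "synthetic" in raw:
            kw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "filter" in raw:
            kw["filter"] = FilterConfig(**raw["filter"])
        if "train" in raw:
            kw["train"] = TrainConfig(**raw["train"])
        if "topology" in raw:
            kw["topology"] = FogTopology.from_dict(raw["topology"])
        if "workload" in raw:
            kw["workload"] = Workload(**raw["workload"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk).

    Any stage failure aborts with a :class:`StageError` naming the stage;
    artifacts of completed stages are preserved in ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    artifacts: list[Path] = []

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("generate"):
        spec = config.synthetic.replace(seed=config.stage_seed("generate"))
        dataset = generate_dataset(spec)
        io.save_dataset(dataset, out / "data")
        artifacts.append(out / "data" / io.MANIFEST_NAME)
        report["stages"]["generate"] = {
            "n_records": len(dataset),
            "class_counts": dataset.class_counts(),
            "seed": spec.seed,
        }

    with stage("filter"):
        logger.info(
            "filter defaults in use: band [%s, %s] Hz, order %s, zero_phase=%s, "
            "notch=%s, global amplitude scaling",
            config.filter.low_cut,
            config.filter.high_cut,
            config.filter.order,
            config.filter.zero_phase,
            config.filter.notch_hz,
        )
        processed = preprocess_dataset(dataset, config.filter, config.filter_signal)
        report["stages"]["filter"] = processed.manifest["preprocessing"]

    with stage("train_autoencoder"):
        train_cfg = TrainConfig(
            epochs=config.train.epochs,
            batch_size=config.train.batch_size,
            learning_rate=config.train.learning_rate,
            seed=config.stage_seed("train_autoencoder"),
            validation_fraction=config.train.validation_fraction,
        )
        encoder, decoder, history = train_autoencoder(processed, train_cfg)
        save_model(out / "model.npz", encoder, decoder)
        artifacts.append(out / "model.npz")
        report["stages"]["train_autoencoder"] = {
            "epochs": train_cfg.epochs,
            "first_loss": history.first,
            "final_loss": history.final,
            "seed": train_cfg.seed,
        }

    with stage("encode"):
        images = encode_dataset(encoder, processed)
        np.save(out / "latent_images.npy", images)
        report["stages"]["encode"] = {"n_images": len(images)}

    with stage("benchmark"):
        specs = default_specs(seed=config.stage_seed("classifier"))
        reports = evaluate_suite(
            processed, encoder, specs, split_seed=config.stage_seed("split")
        )
        table = reports_to_table(reports)
        table.to_csv(out / "benchmark.csv")
        artifacts.append(out / "benchmark.csv")
        with open(out / "benchmark.json", "w") as fh:
            json.dump({a: r.to_dict() for a, r in reports.items()}, fh, indent=2)
        report["stages"]["benchmark"] = {
            a: r.accuracy for a, r in reports.items()
        }

    with stage("analyze_latent"):
        averages = class_average_images(images, dataset.labels())
        rf_model = train_classifier(
            specs[0], FeatureMatrix.from_images(images, dataset.labels())
        )
        imp = importance_map(rf_model)
        save_matrix(out / "importance_map.csv", imp.values)
        for cls, img in averages.images.items():
            save_matrix(out / f"class_average_{cls}.csv", img)
        artifacts.append(out / "importance_map.csv")
        report["stages"]["analyze_latent"] = {
            "top_pixel": list(imp.top_pixel()),
        }

    with stage("simulate_fog"):
        workload = Workload(
            message_size=config.workload.message_size,
            n_messages=config.workload.n_messages,
            inter_arrival=config.workload.inter_arrival,
            arrival_process=config.workload.arrival_process,
            seed=config.stage_seed("fog_workload"),
        )
        comparison = compare_architectures(config.topology, workload)
        report["stages"]["simulate_fog"] = {
            "fog_mean_ms": comparison["fog_mean_ms"],
            "cloud_mean_ms": comparison["cloud_mean_ms"],
            "ratio": comparison["ratio"],
        }

    report["artifact_hashes"] = {str(p): _sha256(p) for p in artifacts if p.exists()}
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=lambda o: getattr(o, "item", str)())
    return report
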