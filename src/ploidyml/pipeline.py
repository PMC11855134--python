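"""End-to-end pipeline: simulate -> preprocess -> train/compare -> optimize.

All randomness flows from one master seed, split into independent
per-stage streams (simulation, balanced subsampling, train/test split,
GA) via ``numpy.random.SeedSequence``, so a run is reproducible from its
config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .classifiers import knn as knn_mod
from .classifiers import pnn as pnn_mod
from .classifiers import svm as svm_mod
from .errors import DataError, StageError
from .evaluation import MetricsReport, compute_metrics, confusion, metrics_table
from .ga import GAConfig, GAResult, evolve, make_fitness
from .preprocess import (
    PloidyDataset,
    apply_standardizer,
    fit_standardizer,
    pca_outlier_filter,
    stratified_split,
    write_dataset,
)
from .serialize import model_to_dict, standardizer_to_dict
from .synthetic import DoseResponseParams

log = logging.getLogger("ploidyml")

MODEL_NAMES = ("pnn", "knn", "svc")


@dataclass
class PipelineConfig:
    """Everything a run needs; every seed is explicit."""

    seed: int = 0
    generator: dict = field(default_factory=dict)  # DoseResponseParams overrides
    grid: list | None = None  # [(concentration, exposure), ...] override
    replicates: int = 4
    explants: int = 4
    per_class: int = 24
    train_per_class: int = 19
    outlier_alpha: float = 0.025
    sigma_grid: list = field(
        default_factory=lambda: [float(s) for s in pnn_mod.DEFAULT_SIGMA_GRID]
    )
    k_grid: list = field(default_factory=lambda: list(knn_mod.DEFAULT_K_GRID))
    svc_C: float = 1.0
    svc_gamma: float | None = None  # None -> 1 / (2 * mean feature variance)
    knn_offset: float = knn_mod.KNN_FEATURE_OFFSET
    ga: dict = field(default_factory=dict)  # GAConfig overrides (seed is derived)
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def generator_params(self) -> DoseResponseParams:
        return DoseResponseParams(**self.generator)

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ("simulate", "assemble", "split", "ga")
        children = ss.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }


@dataclass
class RunReport:
    """Structured summary of one pipeline run."""

    config: dict
    seeds: dict
    class_counts: dict
    outliers_removed: list
    split_counts: dict
    hyperparameters: dict
    metrics: dict  # model -> phase -> MetricsReport
    ranking: list
    ga_result: GAResult

    def metrics_dict(self) -> dict:
        return {
            model: {phase: rep.to_dict() for phase, rep in phases.items()}
            for model, phases in self.metrics.items()
        }

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "class_counts": self.class_counts,
            "outliers_removed": self.outliers_removed,
            "split_counts": self.split_counts,
            "hyperparameters": self.hyperparameters,
            "metrics": self.metrics_dict(),
            "ranking": self.ranking,
            "ga": {
                "best_genes": [float(g) for g in self.ga_result.best.genes],
                "best_fitness": float(self.ga_result.best.fitness),
                "generations": self.ga_result.generations,
                "seed": self.ga_result.seed,
            },
        }


def rank_models(metrics: dict[str, dict[str, MetricsReport]]) -> list[str]:
    """Models ordered by test accuracy, then test F1, then train accuracy.

    Ties beyond that preserve the stable input order.
    """
    names = list(metrics)
    for name in names:
        if "train" not in metrics[name] or "test" not in metrics[name]:
            raise DataError(f"model {name!r} is missing train/test metrics")
    return sorted(
        names,
        key=lambda n: (
            -metrics[n]["test"].accuracy,
            -metrics[n]["test"].f1,
            -metrics[n]["train"].accuracy,
        ),
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("=== stage: %s ===", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("simulate")
def simulate_stage(cfg: PipelineConfig, seed: int) -> list:
    grid = (
        [synthetic.Treatment(c, t) for c, t in cfg.grid]
        if cfg.grid is not None
        else synthetic.default_treatment_grid()
    )
    records = synthetic.simulate_experiment(
        grid, cfg.replicates, cfg.explants, cfg.generator_params(), seed
    )
    log.info("simulated %d explants over %d treatments (seed %d)",
             len(records), len(grid), seed)
    return records


@_stage("preprocess")
def preprocess_stage(cfg: PipelineConfig, records, assemble_seed: int, split_seed: int):
    dataset = synthetic.assemble_balanced_dataset(records, cfg.per_class, assemble_seed)
    filtered, removed = pca_outlier_filter(dataset, cfg.outlier_alpha)
    split = stratified_split(filtered, cfg.train_per_class, split_seed)
    standardizer = fit_standardizer(split.train)
    log.info("dataset %d rows, %d outliers removed, split %d/%d",
             dataset.n, len(removed), split.train.n, split.test.n)
    return dataset, filtered, removed, split, standardizer


@_stage("train")
def train_stage(cfg: PipelineConfig, split, standardizer):
    z_train = apply_standardizer(standardizer, split.train.X)
    strain = PloidyDataset(z_train, split.train.y)

    sigma = pnn_mod.select_sigma(strain, cfg.sigma_grid)
    pnn = pnn_mod.pnn_fit(strain, sigma)

    ktrain = PloidyDataset(knn_mod.prepare_knn_features(z_train, cfg.knn_offset),
                           split.train.y)
    k = knn_mod.select_k(ktrain, [k for k in cfg.k_grid if k <= ktrain.n - 1])
    knn = knn_mod.knn_fit(ktrain, k)

    svc = svm_mod.svc_fit(strain, C=cfg.svc_C, gamma=cfg.svc_gamma)

    hyper = {
        "pnn_sigma": float(sigma),
        "knn_k": int(k),
        "knn_offset": float(cfg.knn_offset),
        "svc_C": float(svc.C),
        "svc_gamma": float(svc.gamma),
    }
    log.info("selected hyperparameters: %s", hyper)
    return {"pnn": pnn, "knn": knn, "svc": svc}, hyper


@_stage("evaluate")
def evaluate_stage(cfg: PipelineConfig, models, split, standardizer):
    metrics: dict[str, dict[str, MetricsReport]] = {}
    for name in MODEL_NAMES:
        metrics[name] = {}
        for phase, part in (("train", split.train), ("test", split.test)):
            z = apply_standardizer(standardizer, part.X)
            if name == "pnn":
                pred = pnn_mod.pnn_predict(models["pnn"], z)
            elif name == "knn":
                pred = knn_mod.knn_predict(
                    models["knn"], knn_mod.prepare_knn_features(z, cfg.knn_offset)
                )
            else:
                pred = svm_mod.svc_predict(models["svc"], z)
            metrics[name][phase] = compute_metrics(confusion(part.y, pred))
    return metrics


@_stage("optimize")
def optimize_stage(cfg: PipelineConfig, pnn_model, standardizer, seed: int) -> GAResult:
    ga_cfg = GAConfig(**{**cfg.ga, "seed": seed})
    fitness = make_fitness(pnn_model, standardizer)
    result = evolve(fitness, ga_cfg)
    log.info("GA optimum: %.3f µM, %.3f h (fitness %.4f)",
             result.best.genes[0], result.best.genes[1], result.best.fitness)
    return result


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order; identical config implies identical report."""
    seeds = cfg.stage_seeds()
    records = simulate_stage(cfg, seeds["simulate"])
    dataset, filtered, removed, split, standardizer = preprocess_stage(
        cfg, records, seeds["assemble"], seeds["split"]
    )
    models, hyper = train_stage(cfg, split, standardizer)
    metrics = evaluate_stage(cfg, models, split, standardizer)
    ranking = rank_models(metrics)
    # The GA fitness is the PNN tetraploid posterior: only the PNN yields a
    # calibrated class probability, so the optimizer always couples to it.
    ga_result = optimize_stage(cfg, models["pnn"], standardizer, seeds["ga"])

    report = RunReport(
        config=cfg.to_dict(),
        seeds=seeds,
        class_counts=dataset.class_counts(),
        outliers_removed=removed,
        split_counts=split.per_class_counts(),
        hyperparameters=hyper,
        metrics=metrics,
        ranking=ranking,
        ga_result=ga_result,
    )
    if cfg.outdir is not None:
        persist_run(cfg, report, dataset, split, standardizer, models)
    return report


def persist_run(cfg, report, dataset, split, standardizer, models) -> None:
    """Write every artifact of a run under the output directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, out / "dataset.csv")
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": report.seeds,
        "train_indices": report_indices(split.train_indices),
        "test_indices": report_indices(split.test_indices),
        "standardizer": standardizer_to_dict(standardizer),
    }
    (out / "split_manifest.json").write_text(json.dumps(manifest, sort_keys=True))
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for name, model in models.items():
        (models_dir / f"{name}.json").write_text(
            json.dumps(model_to_dict(model), sort_keys=True)
        )
    (out / "metrics.json").write_text(
        json.dumps(report.metrics_dict(), sort_keys=True)
    )
    metrics_table(report.metrics).to_csv(out / "metrics.csv")
    (out / "ga_result.json").write_text(report.ga_result.to_json())
    trace = report.ga_result.trace
    with open(out / "ga_trace.csv", "w") as fh:
        fh.write("generation,best_fitness\n")
        for g, v in enumerate(trace):
            fh.write(f"{g},{v!r}\n")
    (out / "run_report.json").write_text(json.dumps(report.to_dict(), sort_keys=True))


def report_indices(idx) -> list[int]:
    return [int(i) for i in np.asarray(idx)]
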