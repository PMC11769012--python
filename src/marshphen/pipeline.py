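"""End-to-end experiment driver.

Runs the full analysis on a synthetic scene: simulate stacks, tidal
filter + double-logistic phenology, monthly SAR features, stratified
sampling, then a random-forest experiment for each requested feature
plan, with cross-validation on the training split and a confusion-matrix
assessment on the held-out split.  ``run_pipeline`` additionally writes
every artifact (rasters, tables, JSON reports, manifest) to a directory;
identical config + seed reproduces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import stackio
from .accuracy import AccuracyReport, evaluate_labels
from .classify import (
    PLAN_FEATURES,
    assemble_features,
    plan_feature_names,
    predict_map,
    train_and_cv,
)
from .errors import ConfigError
from .features import extract_phenology_rasters, sar_feature_rasters
from .phenology import PHENO_FEATURE_NAMES
from .sar import SAR_FEATURE_NAMES
from .spectral import TidalFilterConfig
from .synthetic import (
    SceneConfig,
    TideModel,
    default_pheno_profiles,
    default_sar_profiles,
    generate_samples,
    generate_scene,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one end-to-end run."""

    grid_shape: tuple[int, int] = (24, 24)
    class_layout: str = "blocks"
    cloud_prob: float = 0.1
    noise_sd: float = 0.03
    sar_noise_sd_db: float = 0.7
    shore_cols: int = 4
    shore_prob: float = 0.85
    inland_prob: float = 0.08
    n_per_class: int = 50
    test_fraction: float = 0.3
    sos_threshold: float = 0.5
    plans: tuple = (1, 2, 3, 4, 5)
    n_trees: int = 500
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.plans:
            plan_feature_names(p)  # raises on anything outside 1-5
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.n_per_class < 2:
            raise ConfigError("n_per_class must be >= 2")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw = dict(raw)
        for key in ("grid_shape", "plans"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["plans"] = [int(p) for p in self.plans]
        return d

    def scene_config(self) -> SceneConfig:
        return SceneConfig(
            grid_shape=self.grid_shape,
            class_layout=self.class_layout,
            cloud_prob=self.cloud_prob,
            seed=self.seed,
        )

    def tide_model(self) -> TideModel:
        return TideModel(
            shore_prob=self.shore_prob,
            inland_prob=self.inland_prob,
            shore_cols=self.shore_cols,
        )


@dataclass
class PlanResult:
    """Outcome of one feature plan."""

    plan_id: int
    cv_report: object
    test_report: AccuracyReport
    class_map: np.ndarray
    n_train: int
    n_test: int


@dataclass
class ExperimentResult:
    """All in-memory artifacts of one experiment run."""

    config: RunConfig
    labels: np.ndarray
    pheno_stack: np.ndarray
    sar_stack: np.ndarray
    excluded: np.ndarray
    qc: pd.DataFrame
    samples: pd.DataFrame
    plan_results: dict[int, PlanResult]


def _accuracy_to_dict(report: AccuracyReport) -> dict:
    rnd = lambda v: None if v is None else round(float(v), 10)
    return {
        "pa": {str(k): rnd(v) for k, v in report.pa.items()},
        "ua": {str(k): rnd(v) for k, v in report.ua.items()},
        "oa": rnd(report.oa),
        "po": rnd(report.po),
        "pe": rnd(report.pe),
        "kappa": rnd(report.kappa),
    }


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full synthetic experiment in memory."""
    scene_cfg = config.scene_config()
    pheno_profiles = default_pheno_profiles(noise_sd=config.noise_sd)
    sar_profiles = default_sar_profiles(noise_sd_db=config.sar_noise_sd_db)
    labels, optical, sar = generate_scene(scene_cfg, pheno_profiles, sar_profiles,
                                          config.tide_model())

    pheno = extract_phenology_rasters(optical, TidalFilterConfig(),
                                      threshold=config.sos_threshold)
    sar_feats = sar_feature_rasters(sar)

    samples = generate_samples(labels, config.n_per_class, seed=config.seed)

    # Keep one common sample set across plans: only pixels where every
    # feature (plan 5) is defined, so the plans see identical samples.
    full_table = assemble_features(5, pheno.stack, sar_feats, samples)
    usable_ids = set(full_table["pixel_id"])
    cols = labels.shape[1]
    pix_ids = samples["row"].to_numpy() * cols + samples["col"].to_numpy()
    usable = samples[pd.Series(pix_ids).isin(usable_ids).to_numpy()].reset_index(drop=True)
    n_dropped = len(samples) - len(usable)
    if n_dropped:
        logger.info("dropped %d sample(s) on excluded/unfit pixels", n_dropped)

    train_idx, test_idx = train_test_split(
        np.arange(len(usable)),
        test_size=config.test_fraction,
        random_state=config.seed,
        stratify=usable["class_code"],
    )
    train_samples = usable.iloc[np.sort(train_idx)].reset_index(drop=True)
    test_samples = usable.iloc[np.sort(test_idx)].reset_index(drop=True)

    plan_results: dict[int, PlanResult] = {}
    class_order = sorted(int(c) for c in usable["class_code"].unique())
    for plan in config.plans:
        plan = int(plan)
        train_table = assemble_features(plan, pheno.stack, sar_feats, train_samples)
        test_table = assemble_features(plan, pheno.stack, sar_feats, test_samples)
        cv_report, model = train_and_cv(
            train_table, seed=config.seed, n_estimators=config.n_trees,
            n_folds=config.n_folds,
        )
        feature_cols = list(plan_feature_names(plan))
        y_pred = model.predict(test_table[feature_cols].to_numpy(dtype=float))
        test_report = evaluate_labels(
            test_table["class_code"].to_numpy(), y_pred, class_order
        )
        cmap = predict_map(model, plan, pheno.stack, sar_feats)
        plan_results[plan] = PlanResult(
            plan_id=plan,
            cv_report=cv_report,
            test_report=test_report,
            class_map=cmap,
            n_train=len(train_table),
            n_test=len(test_table),
        )

    return ExperimentResult(
        config=config,
        labels=labels,
        pheno_stack=pheno.stack,
        sar_stack=sar_feats,
        excluded=pheno.excluded,
        qc=pheno.qc,
        samples=usable,
        plan_results=plan_results,
    )


def experiment_report(result: ExperimentResult) -> dict:
    """JSON-serialisable summary of an experiment."""
    plans = {}
    for plan, pr in sorted(result.plan_results.items()):
        plans[str(plan)] = {
            "features": list(plan_feature_names(plan)),
            "n_train": pr.n_train,
            "n_test": pr.n_test,
            "cross_validation": pr.cv_report.to_dict(),
            "test_accuracy": _accuracy_to_dict(pr.test_report),
        }
    return {"config": result.config.to_dict(), "seed": result.config.seed, "plans": plans}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the experiment and write all artifacts plus a manifest.

    Outputs: labels/excluded class maps, 6-band phenology and 24-band
    SAR feature rasters (TIFF + CSV sidecars), QC and sample tables,
    per-plan class maps, a JSON report and ``manifest.json`` with
    sha256 checksums.  Byte-identical given identical config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_experiment(config)

    written: list[Path] = []

    def note(path: Path) -> None:
        written.append(path)
        sidecar = path.with_suffix(".csv")
        if path.suffix == ".tif" and sidecar.exists():
            written.append(sidecar)

    note(stackio.write_class_map(result.labels, out / "labels.tif"))
    note(stackio.write_class_map(result.excluded.astype(np.uint8), out / "excluded.tif"))
    note(stackio.write_feature_stack(result.pheno_stack, PHENO_FEATURE_NAMES, out / "phenology.tif"))
    note(stackio.write_feature_stack(result.sar_stack, SAR_FEATURE_NAMES, out / "sar_features.tif"))
    result.qc.to_csv(out / "phenology_qc.csv", index=False)
    written.append(out / "phenology_qc.csv")
    result.samples.to_csv(out / "samples.csv", index=False)
    written.append(out / "samples.csv")
    for plan, pr in sorted(result.plan_results.items()):
        note(stackio.write_class_map(pr.class_map, out / f"classmap_plan{plan}.tif"))

    report = experiment_report(result)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    written.append(report_path)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
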