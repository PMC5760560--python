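"""End-to-end orchestration: simulate -> preprocess -> partition -> train ->
committee -> baselines -> report.

Every stage reads and writes file artifacts in one output directory, so each
stage can be re-run independently and a finished run is fully inspectable:

========================  =====================================================
stage                     artifacts
========================  =====================================================
simulate                  excerpts.csv, ratings.csv
preprocess                feature_reduction.json, initial_correlations.csv,
                          scaling.json, features_scaled.csv
partition                 partition.json
train                     networks/network_<dim>_<fs>_fold<k>.json,
                          networks/summary.json
committee                 committee.json
baselines                 baselines.json, stepwise_<dim>_<fs>.json
report                    report.csv, report.json
run-all                   all of the above + run_log.json
========================  =====================================================

All randomness flows from the single pipeline seed through named substreams,
so a fixed (config, seed) pair reproduces every artifact byte for byte
(wall-clock timings live only in run_log.json).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines as bl
from . import committee as cm
from . import mlp
from . import preprocess as pp
from . import synthetic_data as sd
from .partition import Partition, make_partition, training_set

__all__ = [
    "PipelineConfig", "PreprocessConfig", "CommitteeConfig", "StepwiseConfig",
    "PipelineError", "run_all",
    "stage_simulate", "stage_preprocess", "stage_partition", "stage_train",
    "stage_committee", "stage_baselines", "stage_report",
]

DIMENSIONS = ("valence", "arousal")
FEATURE_SETS = ("audio", "physio")


class PipelineError(RuntimeError):
    """A stage failed or a required upstream artifact is missing."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


@dataclass
class PreprocessConfig:
    threshold: float = 0.8
    scaling_scope: str = "all"  # "all" (dataset-level, as described) | "train"


@dataclass
class CommitteeConfig:
    fit_scope: str = "all"  # "all" = all 60 excerpts (as described) | "train"


@dataclass
class StepwiseConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: sd.GeneratorConfig = field(default_factory=sd.GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    training: mlp.TrainingConfig = field(default_factory=mlp.TrainingConfig)
    committee: CommitteeConfig = field(default_factory=CommitteeConfig)
    forest: bl.ForestConfig = field(default_factory=bl.ForestConfig)
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["genres"] = list(self.generator.genres)
        d["generator"]["audio_feature_names"] = list(self.generator.audio_feature_names)
        d["generator"]["physio_feature_names"] = list(self.generator.physio_feature_names)
        d["generator"]["collinear_block"] = list(self.generator.collinear_block)
        d["generator"]["mixing_valence"] = list(self.generator.mixing_valence)
        d["generator"]["mixing_arousal"] = list(self.generator.mixing_arousal)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        gen = dict(d.get("generator", {}))
        for key in ("mixing_valence", "mixing_arousal"):
            if key in gen:
                gen[key] = tuple(gen[key])
        for key in ("genres", "audio_feature_names", "physio_feature_names",
                    "collinear_block"):
            if key in gen:
                gen[key] = tuple(gen[key])
        return cls(
            seed=int(d.get("seed", cfg.seed)),
            generator=replace(cfg.generator, **gen),
            preprocess=replace(cfg.preprocess, **d.get("preprocess", {})),
            training=replace(cfg.training, **d.get("training", {})),
            committee=replace(cfg.committee, **d.get("committee", {})),
            forest=replace(cfg.forest, **d.get("forest", {})),
            stepwise=replace(cfg.stepwise, **d.get("stepwise", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _derive_seed(seed: int, name: str) -> int:
    return int(sd.substream(seed, name).integers(2 ** 31))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name!r}; run the {producer!r} subcommand first",
            stage=producer)
    return path


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


# ---------------------------------------------------------------- stages

def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    gen = replace(config.generator, seed=config.seed)
    excerpts, design = sd.generate_dataset(gen)
    sd.write_dataset(excerpts, design, out_dir)


def stage_preprocess(config: PipelineConfig, out_dir: Path) -> None:
    excerpts = pd.read_csv(_require(out_dir / "excerpts.csv", "simulate"))
    gen = config.generator
    audio_names = list(gen.audio_feature_names)
    physio_names = list(gen.physio_feature_names)
    thr = config.preprocess.threshold

    audio_report = pp.correlation_matrix(excerpts[audio_names])
    audio_kept, audio_trace = pp.reduce_features(audio_report, thr)
    physio_report = pp.correlation_matrix(excerpts[physio_names])
    physio_kept, physio_trace = pp.reduce_features(physio_report, thr)
    _write_json(out_dir / "feature_reduction.json", {
        "threshold": thr,
        "audio_retained": audio_kept, "audio_removed": [t["feature"] for t in audio_trace],
        "audio_trace": audio_trace,
        "physio_retained": physio_kept,
        "physio_removed": [t["feature"] for t in physio_trace],
        "physio_trace": physio_trace,
    })

    corr = pp.feature_rating_correlations(
        excerpts[audio_names + physio_names],
        excerpts[["valence_mean", "arousal_mean"]].rename(
            columns={"valence_mean": "valence", "arousal_mean": "arousal"}))
    corr.to_csv(out_dir / "initial_correlations.csv", index=False, float_format="%.17g")

    kept = audio_kept + physio_kept
    if config.preprocess.scaling_scope == "train":
        part = Partition.load(_require(out_dir / "partition.json", "partition"))
        fit_rows = excerpts[excerpts["excerpt_id"].isin(part.train_pool_ids)]
    elif config.preprocess.scaling_scope == "all":
        fit_rows = excerpts
    else:
        raise PipelineError(
            f"unknown scaling_scope {config.preprocess.scaling_scope!r}", "preprocess")
    params = pp.fit_minmax(fit_rows, kept)
    scaled = pp.apply_minmax(params, excerpts)
    scaled.insert(0, "excerpt_id", excerpts["excerpt_id"])
    scaled.insert(1, "genre", excerpts["genre"])
    scaled["valence01"] = pp.rescale_rating(excerpts["valence_mean"])
    scaled["arousal01"] = pp.rescale_rating(excerpts["arousal_mean"])
    scaled.to_csv(out_dir / "features_scaled.csv", index=False, float_format="%.17g")
    _write_json(out_dir / "scaling.json",
                {"scope": config.preprocess.scaling_scope, **params.to_dict()})


def stage_partition(config: PipelineConfig, out_dir: Path) -> None:
    excerpts = pd.read_csv(_require(out_dir / "excerpts.csv", "simulate"))
    part = make_partition(excerpts, seed=config.seed)
    part.save(out_dir / "partition.json")


def _load_reduction(out_dir: Path) -> dict:
    return json.loads(_require(out_dir / "feature_reduction.json", "preprocess").read_text())


def _load_scaled(out_dir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(out_dir / "features_scaled.csv", "preprocess")
                       ).set_index("excerpt_id")


def _arm_features(reduction: dict, fs: str) -> list[str]:
    return reduction[f"{fs}_retained"]


def stage_train(config: PipelineConfig, out_dir: Path) -> None:
    scaled = _load_scaled(out_dir)
    reduction = _load_reduction(out_dir)
    part = Partition.load(_require(out_dir / "partition.json", "partition"))
    net_dir = out_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    summary: dict = {"fold_rmse": {}, "convergence": {}, "epochs": {}}
    for fs in FEATURE_SETS:
        feats = _arm_features(reduction, fs)
        for dim in DIMENSIONS:
            fold_rmses = []
            for k in range(part.n_folds):
                train_ids = training_set(part, k)
                X = scaled.loc[train_ids, feats].to_numpy(dtype=float)
                Y = scaled.loc[train_ids, f"{dim}01"].to_numpy(dtype=float)
                rng = sd.substream(config.seed, f"train/{fs}/{dim}/fold{k}")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    model = mlp.train(X, Y, config.training,
                                      feature_names=feats, dimension=dim, rng=rng)
                model.save(net_dir / f"network_{dim}_{fs}_fold{k}.json")
                Xv = scaled.loc[part.folds[k], feats].to_numpy(dtype=float)
                Yv = scaled.loc[part.folds[k], f"{dim}01"].to_numpy(dtype=float)
                fold_rmses.append(mlp.rmse(model.predict(Xv), Yv))
                summary["convergence"][f"{dim}_{fs}_fold{k}"] = model.trace.converged
                summary["epochs"][f"{dim}_{fs}_fold{k}"] = model.trace.epochs_run
            summary["fold_rmse"][f"{dim}_{fs}"] = {
                "folds": fold_rmses,
                "mean": float(np.mean(fold_rmses)),
                "se": float(np.std(fold_rmses, ddof=1) / np.sqrt(len(fold_rmses))),
            }
    _write_json(net_dir / "summary.json", summary)


def _load_ensembles(out_dir: Path, n_folds: int = 5) -> dict:
    net_dir = out_dir / "networks"
    ensembles: dict = {}
    for fs in FEATURE_SETS:
        for dim in DIMENSIONS:
            members = []
            for k in range(n_folds):
                members.append(mlp.NetworkModel.load(
                    _require(net_dir / f"network_{dim}_{fs}_fold{k}.json", "train")))
            ensembles[(dim, fs)] = cm.EnsembleModel(members=members)
    return ensembles


def stage_committee(config: PipelineConfig, out_dir: Path) -> None:
    scaled = _load_scaled(out_dir)
    part = Partition.load(_require(out_dir / "partition.json", "partition"))
    ensembles = _load_ensembles(out_dir)
    fit_ids = sorted(scaled.index) if config.committee.fit_scope == "all" \
        else sorted(part.train_pool_ids)
    result: dict = {"fit_scope": config.committee.fit_scope, "dimensions": {}}
    for dim in DIMENSIONS:
        p_ens, f_ens = ensembles[(dim, "audio")], ensembles[(dim, "physio")]

        def outs(ens: cm.EnsembleModel, ids: list[str]) -> np.ndarray:
            X = scaled.loc[ids, ens.feature_names].to_numpy(dtype=float)
            return cm.ensemble_predict(ens, X)

        t_fit = scaled.loc[fit_ids, f"{dim}01"].to_numpy(dtype=float)
        p_fit, f_fit = outs(p_ens, fit_ids), outs(f_ens, fit_ids)
        model = cm.fit_cmlr(p_fit, f_fit, t_fit, dimension=dim)
        contrib = cm.contributions(model)

        cmea_in = mlp.rmse(cm.cmea_predict(p_fit, f_fit), t_fit)
        cmlr_in = mlp.rmse(cm.cmlr_predict(model, p_fit, f_fit), t_fit)
        if cmlr_in > cmea_in + 1e-9:
            raise PipelineError(
                f"CMLR in-sample RMSE ({cmlr_in:.4f}) exceeds CMEA's ({cmea_in:.4f}) "
                f"for {dim}: OLS optimality violated", "committee")

        test_ids = part.test_ids
        t_test = scaled.loc[test_ids, f"{dim}01"].to_numpy(dtype=float)
        p_test, f_test = outs(p_ens, test_ids), outs(f_ens, test_ids)
        result["dimensions"][dim] = {
            "b_perc": model.b_perc, "b_feel": model.b_feel,
            "intercept": model.intercept,
            "perc_pct": contrib.perc_pct, "feel_pct": contrib.feel_pct,
            "perc_pct_rounded": cm.round_half_up(contrib.perc_pct),
            "feel_pct_rounded": cm.round_half_up(contrib.feel_pct),
            "insample_rmse": {"CMEA": cmea_in, "CMLR": cmlr_in},
            "test_rmse": {
                "perception_ensemble": mlp.rmse(p_test, t_test),
                "feeling_ensemble": mlp.rmse(f_test, t_test),
                "CMEA": mlp.rmse(cm.cmea_predict(p_test, f_test), t_test),
                "CMLR": mlp.rmse(cm.cmlr_predict(model, p_test, f_test), t_test),
            },
        }
    _write_json(out_dir / "committee.json", result)


def stage_baselines(config: PipelineConfig, out_dir: Path) -> None:
    scaled = _load_scaled(out_dir)
    reduction = _load_reduction(out_dir)
    part = Partition.load(_require(out_dir / "partition.json", "partition"))
    test_ids = part.test_ids
    pool_ids = sorted(part.train_pool_ids)
    result: dict = {"stepwise": {}, "forest": {}}
    for fs in FEATURE_SETS:
        feats = _arm_features(reduction, fs)
        X_test = scaled.loc[test_ids, feats]
        for dim in DIMENSIONS:
            y_test = scaled.loc[test_ids, f"{dim}01"].to_numpy(dtype=float)
            # stepwise: one model per CV fold on its 36-excerpt training set
            fold_models = []
            for k in range(part.n_folds):
                ids = training_set(part, k)
                fold_models.append(bl.stepwise_forward(
                    scaled.loc[ids, feats],
                    scaled.loc[ids, f"{dim}01"].to_numpy(dtype=float),
                    p_enter=config.stepwise.p_enter,
                    p_remove=config.stepwise.p_remove))
            _write_json(out_dir / f"stepwise_{dim}_{fs}.json",
                        {"folds": [m.to_dict() for m in fold_models]})
            ens_pred = bl.stepwise_ensemble_predict(fold_models, X_test)
            result["stepwise"][f"{dim}_{fs}"] = {
                "n_models": sum(not m.no_model for m in fold_models),
                "test_rmse": None if ens_pred is None else mlp.rmse(ens_pred, y_test),
            }
            # random forest: trained once on the 44-excerpt pool, no CV
            fcfg = replace(config.forest,
                           seed=_derive_seed(config.seed, f"forest/{fs}/{dim}"))
            forest = bl.fit_forest(scaled.loc[pool_ids, feats],
                                   scaled.loc[pool_ids, f"{dim}01"].to_numpy(dtype=float),
                                   fcfg)
            result["forest"][f"{dim}_{fs}"] = {
                "test_rmse": mlp.rmse(bl.forest_predict(forest, X_test), y_test),
            }
    result["test_ids"] = test_ids
    _write_json(out_dir / "baselines.json", result)


def stage_report(config: PipelineConfig, out_dir: Path) -> bl.ResultsReport:
    committee = json.loads(_require(out_dir / "committee.json", "committee").read_text())
    base = json.loads(_require(out_dir / "baselines.json", "baselines").read_text())
    part = Partition.load(_require(out_dir / "partition.json", "partition"))

    cells: dict = {"neural_network": {}, "stepwise_regression": {}, "random_forest": {}}
    n_models: dict = {"neural_network": {}, "stepwise_regression": {}, "random_forest": {}}
    ens_key = {"audio": "perception_ensemble", "physio": "feeling_ensemble"}
    for fs in FEATURE_SETS:
        for method in cells:
            cells[method].setdefault(fs, {})
            n_models[method].setdefault(fs, {})
        for dim in DIMENSIONS:
            dims = committee["dimensions"][dim]
            cells["neural_network"][fs][dim] = dims["test_rmse"][ens_key[fs]]
            n_models["neural_network"][fs][dim] = part.n_folds
            sw = base["stepwise"][f"{dim}_{fs}"]
            cells["stepwise_regression"][fs][dim] = sw["test_rmse"]
            n_models["stepwise_regression"][fs][dim] = sw["n_models"]
            cells["random_forest"][fs][dim] = base["forest"][f"{dim}_{fs}"]["test_rmse"]
            n_models["random_forest"][fs][dim] = 1
    committee_rows = {
        "CMEA": {d: committee["dimensions"][d]["test_rmse"]["CMEA"] for d in DIMENSIONS},
        "CMLR": {d: committee["dimensions"][d]["test_rmse"]["CMLR"] for d in DIMENSIONS},
        "contributions": {
            d: {"perc_pct": committee["dimensions"][d]["perc_pct_rounded"],
                "feel_pct": committee["dimensions"][d]["feel_pct_rounded"]}
            for d in DIMENSIONS},
    }
    report = bl.build_report(cells, committee_rows, n_models,
                             {"committee": part.test_ids, "baselines": base["test_ids"]})
    report.to_frame().to_csv(out_dir / "report.csv", index=False, float_format="%.17g")
    _write_json(out_dir / "report.json", {
        "cells": report.cells, "committee": report.committee,
        "n_models": report.n_models, "test_ids": report.test_ids,
    })
    return report


_STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("partition", stage_partition),
    ("train", stage_train),
    ("committee", stage_committee),
    ("baselines", stage_baselines),
    ("report", stage_report),
]

# partition before preprocess so train-scoped scaling can see the split
_RUN_ORDER = ["simulate", "partition", "preprocess", "train",
              "committee", "baselines", "report"]


def run_all(config: PipelineConfig, out_dir: str | Path) -> bl.ResultsReport:
    """Run every stage in order and write run_log.json; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save_yaml(out / "config.yaml")
    stages = dict(_STAGES)
    log: dict = {"seed": config.seed, "stages": {}}
    report = None
    for name in _RUN_ORDER:
        t0 = time.perf_counter()
        try:
            result = stages[name](config, out)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}", stage=name) from exc
        log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        if name == "report":
            report = result
    summary_path = out / "networks" / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        log["network_convergence"] = summary["convergence"]
        log["network_epochs"] = summary["epochs"]
    _write_json(out / "run_log.json", log)
    return report
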