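"""Config-driven pipeline stages over on-disk artifacts.

Each stage is a pure function of (input artifacts, config, seeds): it reads
the upstream files from the working directory, writes its own outputs
there, and records a manifest (config hash, seeds, package version) so a
re-run with the same config reproduces the artifacts byte-for-byte.

Stage graph::

    simulate -> extract -> robustness -> select -> train -> evaluate

``simulate`` materializes a synthetic cohort (NIfTI volumes/masks plus a
manifest CSV); on real data the same manifest layout is the entry point
and ``simulate`` is skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .evaluate import (
    covariate_adjusted_regression,
    evaluate_predictions,
    roc_curve_points,
)
from .image import MODALITIES, ROIMask, VolumeImage
from .model import (
    GPParams,
    TrainedModel,
    fit_logistic,
    fit_symbolic,
    predict,
    split_train_test,
)
from .phantom import CohortSpec, write_cohort
from .preprocess import normalize_to_nawm, reslice_isotropic
from .robustness import canonical_perturbations, perturb_mask, robust_features
from .selection import select_features
from .texture import all_feature_names, modality_features_from_resliced

log = logging.getLogger("gliotex")


class PipelineConfig(BaseModel):
    """Schema-validated configuration for the whole pipeline.

    Every stochastic stage has its own explicit seed so stages can be
    re-run in isolation.
    """

    workdir: str = "gliotex_run"
    n_patients: int = Field(default=40, ge=2)
    gray_levels: int = Field(default=8, ge=2)
    target_mm: float = Field(default=1.0, gt=0)
    icc_threshold: float = Field(default=0.6, ge=-1.0, le=1.0)
    corr_threshold: float = Field(default=0.6, ge=0.0, le=1.0)
    selection_max_rounds: int = Field(default=100, ge=1)
    selection_alpha: float = Field(default=0.01, gt=0.0, lt=1.0)
    selection_trees: int = Field(default=100, ge=10)
    model_engine: str = "symbolic"
    gp_population: int = Field(default=500, ge=10)
    gp_generations: int = Field(default=50, ge=1)
    gp_max_depth: int = Field(default=6, ge=2)
    gp_tournament: int = Field(default=3, ge=2)
    bootstrap_b: int = Field(default=2000, ge=100)
    cohort_seed: int = 0
    perturb_seed: int = 1
    selection_seed: int = 2
    split_seed: int = 3
    gp_seed: int = 4
    eval_seed: int = 5

    @field_validator("model_engine")
    @classmethod
    def _engine(cls, v: str) -> str:
        if v not in ("symbolic", "logistic"):
            raise ValueError("model_engine must be 'symbolic' or 'logistic'")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, stage: str, t0: float, outputs: List[str]) -> None:
    wd = Path(cfg.workdir)
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "config": cfg.model_dump(),
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": outputs,
    }
    with open(wd / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _require(path: Path, stage: str, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs '{path}'; run `{hint}` first"
        )
    return path


def _load_patient(wd: Path, row: pd.Series):
    volumes = {
        mod: VolumeImage.from_nifti(wd / "cohort" / row[f"{mod}_path"], modality=mod)
        for mod in MODALITIES
    }
    tumors = {
        mod: ROIMask.from_nifti(wd / "cohort" / row[f"{mod}_tumor_path"], role="tumor")
        for mod in MODALITIES
    }
    nawm = ROIMask.from_nifti(wd / "cohort" / row["nawm_path"], role="nawm")
    return volumes, tumors, nawm


def _read_manifest_csv(cfg: PipelineConfig, stage: str) -> pd.DataFrame:
    wd = Path(cfg.workdir)
    path = _require(wd / "cohort" / "manifest.csv", stage, "gliotex simulate")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate the synthetic cohort on disk."""
    t0 = time.time()
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    cspec = CohortSpec(n_patients=cfg.n_patients, seed=cfg.cohort_seed)
    manifest = write_cohort(cspec, wd / "cohort")
    log.info("simulate: %d patients -> %s", cfg.n_patients, manifest)
    _write_manifest(cfg, "simulate", t0, [str(manifest)])
    return manifest


def _patient_features(volumes, tumors, nawm, cfg: PipelineConfig) -> Dict[str, float]:
    feats: Dict[str, float] = {}
    for mod in MODALITIES:
        normed = normalize_to_nawm(volumes[mod], tumors[mod], nawm)
        resliced, (tumor_r, _) = reslice_isotropic(
            normed, (tumors[mod], nawm), cfg.target_mm
        )
        feats.update(
            modality_features_from_resliced(resliced, tumor_r, cfg.gray_levels).values
        )
    return feats


def stage_extract(cfg: PipelineConfig) -> Path:
    """86-feature table from the cohort volumes."""
    t0 = time.time()
    wd = Path(cfg.workdir)
    mdf = _read_manifest_csv(cfg, "extract")
    rows = []
    for _, row in mdf.iterrows():
        volumes, tumors, nawm = _load_patient(wd, row)
        feats = _patient_features(volumes, tumors, nawm, cfg)
        rows.append({"patient_id": row["patient_id"], **feats})
    out = pd.DataFrame(rows)[["patient_id"] + all_feature_names()]
    path = wd / "features.csv"
    out.to_csv(path, index=False)
    log.info("extract: %d patients x %d features", len(out), out.shape[1] - 1)
    _write_manifest(cfg, "extract", t0, [str(path)])
    return path


def stage_robustness(cfg: PipelineConfig) -> Path:
    """Perturbed-ROI re-extraction and ICC screening."""
    t0 = time.time()
    wd = Path(cfg.workdir)
    mdf = _read_manifest_csv(cfg, "robustness")
    _require(wd / "features.csv", "robustness", "gliotex extract")
    specs = canonical_perturbations(cfg.perturb_seed)
    versions: List[List[Dict[str, float]]] = [[] for _ in range(1 + len(specs))]
    ids = []
    for _, row in mdf.iterrows():
        ids.append(row["patient_id"])
        volumes, tumors, nawm = _load_patient(wd, row)
        per_mod = {}
        for mod in MODALITIES:
            normed = normalize_to_nawm(volumes[mod], tumors[mod], nawm)
            resliced, (tumor_r, _) = reslice_isotropic(
                normed, (tumors[mod], nawm), cfg.target_mm
            )
            per_mod[mod] = (resliced, tumor_r)
        for v, spec in enumerate([None] + specs):
            feats: Dict[str, float] = {}
            for mod in MODALITIES:
                resliced, tumor_r = per_mod[mod]
                m = tumor_r if spec is None else perturb_mask(tumor_r, spec)
                feats.update(
                    modality_features_from_resliced(
                        resliced, m, cfg.gray_levels
                    ).values
                )
            versions[v].append(feats)
    tables = [
        pd.DataFrame(v, index=ids)[all_feature_names()] for v in versions
    ]
    retained, report = robust_features(tables, threshold=cfg.icc_threshold)
    report_path = wd / "robustness.csv"
    report.to_csv(report_path, index=False)
    with open(wd / "robust_features.json", "w") as fh:
        json.dump({"threshold": cfg.icc_threshold, "features": retained}, fh, indent=1)
    log.info("robustness: %d/%d features retained at ICC >= %.2f",
             len(retained), len(report), cfg.icc_threshold)
    _write_manifest(cfg, "robustness", t0, [str(report_path)])
    return report_path


def stage_select(cfg: PipelineConfig) -> Path:
    """Shadow-feature selection + correlation pruning on robust features."""
    t0 = time.time()
    wd = Path(cfg.workdir)
    mdf = _read_manifest_csv(cfg, "select")
    feats = pd.read_csv(_require(wd / "features.csv", "select", "gliotex extract"))
    rob_path = _require(wd / "robust_features.json", "select", "gliotex robustness")
    with open(rob_path) as fh:
        robust = json.load(fh)["features"]
    X = feats.set_index("patient_id")[robust]
    y = mdf.set_index("patient_id").loc[X.index, "cd3_z"]
    retained, result = select_features(
        X,
        y,
        max_rounds=cfg.selection_max_rounds,
        seed=cfg.selection_seed,
        r_threshold=cfg.corr_threshold,
        alpha=cfg.selection_alpha,
        n_estimators=cfg.selection_trees,
    )
    with open(wd / "selection.json", "w") as fh:
        fh.write(result.to_json())
    with open(wd / "selected_features.json", "w") as fh:
        json.dump({"features": retained}, fh, indent=1)
    log.info("select: %d confirmed, %d after pruning",
             len(result.confirmed), len(retained))
    _write_manifest(cfg, "select", t0, [str(wd / "selected_features.json")])
    return wd / "selected_features.json"


def stage_train(cfg: PipelineConfig) -> Path:
    """50/50 split and model fit on the training half."""
    t0 = time.time()
    wd = Path(cfg.workdir)
    mdf = _read_manifest_csv(cfg, "train").set_index("patient_id")
    feats = pd.read_csv(
        _require(wd / "features.csv", "train", "gliotex extract")
    ).set_index("patient_id")
    with open(_require(wd / "selected_features.json", "train", "gliotex select")) as fh:
        selected = json.load(fh)["features"]
    if not selected:
        raise ValueError("no selected features; cannot train a model")
    table = mdf.join(feats[selected])
    train, test, balance = split_train_test(
        table, seed=cfg.split_seed, balance_vars=["age", "kps"] + selected
    )
    if cfg.model_engine == "symbolic":
        mdl = fit_symbolic(
            train[selected],
            train["cd3_label"],
            GPParams(
                population=cfg.gp_population,
                generations=cfg.gp_generations,
                max_depth=cfg.gp_max_depth,
                tournament=cfg.gp_tournament,
            ),
            seed=cfg.gp_seed,
        )
    else:
        mdl = fit_logistic(train[selected], train["cd3_label"], seed=cfg.gp_seed)
    with open(wd / "model.json", "w") as fh:
        fh.write(mdl.to_json())
    split = {
        "train_ids": train.index.tolist(),
        "test_ids": test.index.tolist(),
        "balance_p": balance,
        "seed": cfg.split_seed,
    }
    with open(wd / "split.json", "w") as fh:
        json.dump(split, fh, indent=1)
    log.info("train: engine=%s train AUC %.3f", cfg.model_engine, mdl.train_auc)
    _write_manifest(cfg, "train", t0, [str(wd / "model.json")])
    return wd / "model.json"


def stage_evaluate(cfg: PipelineConfig) -> Path:
    """Held-out evaluation: ROC/AUC, confusion metrics, concordance,
    covariate-adjusted regression."""
    t0 = time.time()
    wd = Path(cfg.workdir)
    mdf = _read_manifest_csv(cfg, "evaluate").set_index("patient_id")
    feats = pd.read_csv(
        _require(wd / "features.csv", "evaluate", "gliotex extract")
    ).set_index("patient_id")
    with open(_require(wd / "model.json", "evaluate", "gliotex train")) as fh:
        mdl = TrainedModel.from_json(fh.read())
    with open(_require(wd / "split.json", "evaluate", "gliotex train")) as fh:
        split = json.load(fh)
    test_ids = split["test_ids"]
    X_test = feats.loc[test_ids]
    y_true = mdf.loc[test_ids, "cd3_label"].to_numpy()
    y_cont = mdf.loc[test_ids, "cd3_z"].to_numpy()
    scores, labels = predict(mdl, X_test)
    report = evaluate_predictions(
        scores, labels, y_true, y_cont, n_boot=cfg.bootstrap_b, seed=cfg.eval_seed
    )
    covs = pd.DataFrame(
        {
            "age": mdf.loc[test_ids, "age"],
            "gender": mdf.loc[test_ids, "sex"],
            "kps": mdf.loc[test_ids, "kps"],
            "flair_tumor_volume": X_test["flair_regional_tumor_volume_mm3"],
            "flair_total_intensity": X_test["flair_regional_total_intensity"],
            "t1post_tumor_volume": X_test["t1post_regional_tumor_volume_mm3"],
            "t1post_total_intensity": X_test["t1post_regional_total_intensity"],
        }
    )
    report.adjustment_p = covariate_adjusted_regression(y_cont, scores, covs)
    report.balance_p = split["balance_p"]
    with open(wd / "eval.json", "w") as fh:
        fh.write(report.to_json())
    with open(wd / "eval.txt", "w") as fh:
        fh.write(report.to_text() + "\n")
    roc_curve_points(scores, y_true).to_csv(wd / "roc.csv", index=False)
    log.info("evaluate: test AUC %.3f accuracy %.1f%%",
             report.auc, 100 * report.accuracy)
    _write_manifest(cfg, "evaluate", t0, [str(wd / "eval.json")])
    return wd / "eval.json"


STAGES = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "robustness": stage_robustness,
    "select": stage_select,
    "train": stage_train,
    "evaluate": stage_evaluate,
}


def run_stage(stage_name: str, cfg: PipelineConfig) -> Path:
    """Run one named stage (or ``all``) and return its primary artifact."""
    if stage_name == "all":
        out = None
        for name in STAGES:
            out = STAGES[name](cfg)
        return out
    if stage_name not in STAGES:
        raise ValueError(f"unknown stage '{stage_name}'; choose from {list(STAGES)} or 'all'")
    return STAGES[stage_name](cfg)
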