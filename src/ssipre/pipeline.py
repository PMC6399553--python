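"""End-to-end orchestration: simulate -> preprocess -> featurize -> evaluate.

A single schema-validated :class:`RunConfig` (YAML or JSON) drives a fully
reproducible run; one master seed deterministically derives the per-stage
seeds.  Every run writes the resolved configuration next to its outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import evaluate as ev
from . import io as sio
from .catalog import default_catalog, read_catalog_json, write_catalog_json
from .features import WindowSpec, build_feature_matrix
from .model import compute_penalty_factors, select_lambda_cv
from .preprocess import aggregate_daily, impute_hybrid, impute_knn, impute_locf
from .synth import CohortSpec, EffectSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SynthConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the cause."""


class SynthConfig(BaseModel):
    n_patients: int = Field(gt=0)
    prevalence: float = Field(default=0.2013, gt=0, lt=1)
    crp_shift_M: float = Field(default=1.0, ge=0)
    test_rate_multiplier: float = Field(default=1.5, ge=1)
    abn_prob_shift: float = Field(default=0.1, ge=0, le=1)

    def effects(self) -> EffectSpec:
        return EffectSpec(
            crp_shift_M=self.crp_shift_M,
            test_rate_multiplier=self.test_rate_multiplier,
            abn_prob_shift=self.abn_prob_shift,
        )


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run."""

    labs_path: Optional[str] = None
    patients_path: Optional[str] = None
    catalog_path: Optional[str] = None
    synth: Optional[SynthConfig] = None

    imputation: Literal["locf", "knn", "hybrid"] = "hybrid"
    knn_k: int = Field(default=5, ge=1)
    obs_days: int = Field(default=60, gt=0)
    windows: dict[str, tuple[int, int]] = Field(default_factory=dict)

    feature_set: Literal["CRP", "BLM", "FLM", "crp", "blm", "flm"] = "FLM"
    p_max: Optional[int] = Field(default=None, ge=0)
    price_penalty: bool = False
    rose: bool = False

    n_repeats: int = Field(default=100, ge=1)
    train_fraction: float = Field(default=0.8, gt=0, lt=1)
    folds: int = Field(default=10, ge=2)
    n_lambdas: int = Field(default=100, ge=2)
    seed: int = 0
    out_dir: str = "ssipre_run"

    @model_validator(mode="after")
    def _check_inputs(self) -> "RunConfig":
        if self.synth is None and (self.labs_path is None or self.patients_path is None):
            raise ValueError("either synth or labs_path+patients_path must be given")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(config.model_dump_json(indent=2))
    synth_seed, exp_seed = _stage_seeds(config.seed, 2)

    catalog = (
        read_catalog_json(config.catalog_path)
        if config.catalog_path
        else default_catalog()
    )
    write_catalog_json(catalog, out / "catalog.json")

    labs, patients = _load_or_simulate(config, catalog, synth_seed, out)
    grid = _preprocess(config, labs, patients, catalog)
    raw, imputed = grid
    X, y = _featurize(config, imputed, raw, catalog, patients)
    result = _evaluate(config, X, y, catalog, labs, exp_seed)

    result.metrics.per_repeat.to_csv(out / "metrics_per_repeat.csv", index=False)
    result.selection.table.to_csv(out / "selection_frequency.csv")
    summary = {
        "feature_set": config.feature_set.upper(),
        "p_max": config.p_max,
        "price_penalty": config.price_penalty,
        "n_patients": int(len(y)),
        "n_validation_total": result.n_validation_total,
        "metrics": {
            k: dict(v) for k, v in result.metrics.summary().to_dict("index").items()
        },
    }
    if result.cost is not None:
        summary["cost"] = {
            "total_nok": result.cost.total_nok,
            "n_patient_evaluations": result.cost.n_patient_evaluations,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    # final model refit on all data, for deployment-style use
    penalty = (
        compute_penalty_factors(catalog, X.columns) if config.price_penalty else None
    )
    final = select_lambda_cv(
        X, y, penalty=penalty, folds=config.folds, p_max=config.p_max,
        seed=exp_seed, n_lambdas=config.n_lambdas,
    )
    final.to_json(out / "model.json")
    logger.info("pipeline run complete: %s", out)
    return out


@_stage("simulate/load")
def _load_or_simulate(config: RunConfig, catalog, synth_seed: int, out: Path):
    if config.synth is not None:
        spec = CohortSpec(
            n_patients=config.synth.n_patients,
            prevalence=config.synth.prevalence,
            obs_days=config.obs_days,
            seed=synth_seed,
            effects=config.synth.effects(),
        )
        patients, labs = generate_cohort(spec, catalog)
        sio.write_labs_csv(labs, out / "labs.csv")
        sio.write_patients_csv(patients, out / "patients.csv")
        logger.info("simulated %d patients, %d measurements", len(patients), len(labs))
    else:
        labs = sio.read_labs_csv(config.labs_path, catalog)
        patients = sio.read_patients_csv(config.patients_path)
        logger.info("loaded %d patients, %d measurements", len(patients), len(labs))
    return labs, patients


@_stage("preprocess")
def _preprocess(config: RunConfig, labs, patients, catalog):
    raw = aggregate_daily(
        labs,
        config.obs_days,
        patient_ids=[p.patient_id for p in patients],
        test_names=[e.test_name for e in catalog],
    )
    if config.imputation == "locf":
        imputed = impute_locf(raw, catalog)
    elif config.imputation == "knn":
        imputed = impute_knn(raw, k=config.knn_k, catalog=catalog)
    else:
        imputed = impute_hybrid(raw, k=config.knn_k, catalog=catalog)
    return raw, imputed


@_stage("featurize")
def _featurize(config: RunConfig, imputed, raw, catalog, patients):
    windows = WindowSpec.for_interval(
        config.obs_days, per_test={k: tuple(v) for k, v in config.windows.items()}
    )
    X = build_feature_matrix(
        imputed, raw, windows, catalog, patients, feature_set=config.feature_set.upper()
    )
    y = pd.Series([p.ssi for p in patients], index=[p.patient_id for p in patients])
    return X, y.to_numpy()


@_stage("evaluate")
def _evaluate(config: RunConfig, X, y, catalog, labs, exp_seed: int):
    spec = ev.ExperimentSpec(
        n_repeats=config.n_repeats,
        train_fraction=config.train_fraction,
        feature_set=config.feature_set.upper(),
        p_max=config.p_max,
        price_penalty=config.price_penalty,
        imputation=config.imputation,
        knn_k=config.knn_k,
        obs_days=config.obs_days,
        seed=exp_seed,
        folds=config.folds,
        n_lambdas=config.n_lambdas,
        rose=config.rose,
    )
    penalty = (
        compute_penalty_factors(catalog, X.columns) if config.price_penalty else None
    )
    return ev.repeated_holdout(X, y, spec, penalty=penalty, labs=labs, catalog=catalog)
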