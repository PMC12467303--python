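"""End-to-end orchestration: simulate -> train -> infer -> evaluate.

A :class:`RunConfig` (schema-validated, unknown keys rejected) describes one
experiment; :func:`run_pipeline` executes the stages, writes every artifact
(dataset, checkpoints, predictions, report JSON, provenance record) under
the configured output directory and returns the report as a dict.

The single global seed fans out deterministically to per-stage sub-seeds via
``numpy.random.SeedSequence(global_seed).spawn(...)`` in the fixed order
(reference, simulation, training, inference), so any stage can be re-run in
isolation with the same draw stream.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .diffusion import make_schedule
from .evaluate import evaluate_predictions, nnls_deconvolve, paired_rmse_ttest
from .io import (export_dataset_csv, load_reference, save_atlas,
                 save_checkpoint, save_dataset, write_matrix_csv)
from .preprocess import PreprocessConfig, build_atlas
from .pseudobulk import SimulationConfig, dataset_arrays, generate_dataset
from .synthetic import SynthRefConfig, simulate_reference, type_centroids
from .train import TrainingConfig, infer_proportions, train_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

_FORBID = ConfigDict(extra="forbid")


class PreprocessSection(BaseModel):
    model_config = _FORBID
    min_genes: int = 200
    max_genes: int = 5000
    max_mito_frac: float = 0.20
    min_cells_per_gene: int = 3
    n_top_hvgs: int = 2000
    min_mean: float = 0.0125
    max_mean: float = 3.0
    min_disp: float = 0.5
    n_bins: int = 20
    allow_type_loss: bool = False


class SyntheticSection(BaseModel):
    model_config = _FORBID
    n_types: int = 5
    n_genes: int = 300
    cells_per_type: int = 100
    n_markers_per_type: int = 20
    marker_fold: float = 20.0
    base_mean: float = 2.0
    baseline_sigma: float = 1.5
    marker_baseline_frac: float = 0.04
    nb_dispersion: float = 0.5
    library_size_cv: float = 0.2
    marker_overlap_frac: float = 0.0


class SimulationSection(BaseModel):
    model_config = _FORBID
    alpha: float = 1.0
    n_cells: int = 2000
    n_train: int = 5000
    n_test: int = 500
    truth: Literal["realized", "latent"] = "realized"


class ScheduleSection(BaseModel):
    model_config = _FORBID
    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    n_draws: int = 1


class ModelSection(BaseModel):
    model_config = _FORBID
    kinds: list[Literal["diffformer", "diffmlp"]] = ["diffformer"]
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 3
    d_ff: int = 256
    mlp_hidden: list[int] = [256, 256]
    dropout: float = 0.1


class TrainingSection(BaseModel):
    model_config = _FORBID
    lr: float = 1e-4
    weight_decay: float = 0.01
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    epochs: int = 150
    batch_size: int = 64
    t_max: int = 150
    eta_min: float = 1e-6
    early_stop_patience: int = 20
    val_fraction: float = 0.1


class RunConfig(BaseModel):
    """Top-level run configuration; every default matches the published
    training recipe where one exists."""
    model_config = _FORBID
    reference: Literal["synthetic", "10x"] = "synthetic"
    reference_path: Optional[str] = None     # 10x triplet dir when reference="10x"
    preprocessing: PreprocessSection = PreprocessSection()
    synthetic: SyntheticSection = SyntheticSection()
    simulation: SimulationSection = SimulationSection()
    schedule: ScheduleSection = ScheduleSection()
    model: ModelSection = ModelSection()
    training: TrainingSection = TrainingSection()
    include_nnls_baseline: bool = True
    seed: int = 42
    out_dir: str = "run_output"


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        return RunConfig(**(yaml.safe_load(f) or {}))


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_path = out / "events.jsonl"
    events = open(events_path, "w")

    def log_event(stage: str, **info) -> None:
        events.write(json.dumps({"stage": stage, **info}, sort_keys=True) + "\n")
        events.flush()
        logger.info("%s: %s", stage, info)

    seed_ref, seed_sim, seed_train, seed_infer = _sub_seeds(config.seed, 4)
    t0 = time.time()
    try:
        # ---- reference ---------------------------------------------------
        if config.reference == "synthetic":
            raw = simulate_reference(SynthRefConfig(
                seed=seed_ref, **config.synthetic.model_dump()))
        else:
            if not config.reference_path:
                raise ValueError("reference_path required for reference='10x'")
            raw = load_reference(config.reference_path)
        atlas = build_atlas(raw, PreprocessConfig(
            **config.preprocessing.model_dump()))
        save_atlas(out / "atlas.h5", atlas)
        log_event("atlas", K=atlas.K, G=atlas.G, n_cells=len(atlas.cell_types))

        # ---- pseudo-bulk simulation --------------------------------------
        sim = SimulationConfig(seed=seed_sim, **config.simulation.model_dump())
        train_samples, test_samples = generate_dataset(atlas, sim)
        save_dataset(out / "dataset.h5", train_samples, test_samples,
                     atlas.type_names, atlas.hvg_ids, sim.__dict__)
        train_bulk, train_props = dataset_arrays(train_samples)
        test_bulk, test_props = dataset_arrays(test_samples)
        export_dataset_csv(out / "test", test_bulk, test_props,
                           atlas.type_names, atlas.hvg_ids)
        log_event("simulate", n_train=len(train_samples),
                  n_test=len(test_samples))

        # ---- train / infer / evaluate ------------------------------------
        schedule = make_schedule(config.schedule.T, config.schedule.beta_start,
                                 config.schedule.beta_end)
        tcfg = TrainingConfig(seed=seed_train,
                              **config.training.model_dump())
        reports: dict[str, dict] = {}
        rmse_by_method: dict[str, np.ndarray] = {}
        for kind in config.model.kinds:
            overrides = (
                {"d_model": config.model.d_model,
                 "n_heads": config.model.n_heads,
                 "n_layers": config.model.n_layers,
                 "d_ff": config.model.d_ff,
                 "dropout": config.model.dropout}
                if kind == "diffformer" else
                {"d_model": config.model.d_model,
                 "hidden": tuple(config.model.mlp_hidden),
                 "dropout": config.model.dropout})
            model, trace = train_model(kind, train_bulk, train_props, tcfg,
                                       schedule, overrides)
            save_checkpoint(out / f"{kind}.ckpt.h5", model, atlas.type_names,
                            atlas.hvg_ids, tcfg.seed,
                            extra={"best_epoch": trace.best_epoch,
                                   "stop_reason": trace.stop_reason})
            log_event("train", model=kind, epochs_run=len(trace.val_loss),
                      best_epoch=trace.best_epoch,
                      best_val_loss=trace.val_loss[trace.best_epoch])
            pred = infer_proportions(model, test_bulk, schedule,
                                     seed=seed_infer,
                                     n_draws=config.schedule.n_draws)
            write_matrix_csv(out / f"{kind}.predictions.csv", pred,
                             atlas.type_names)
            rep = evaluate_predictions(test_props, pred, atlas.type_names)
            reports[kind] = rep.to_dict()
            rmse_by_method[kind] = rep.per_sample_rmse
            log_event("evaluate", model=kind, overall_rmse=rep.overall_rmse,
                      overall_pcc=rep.overall_pcc)

        if config.include_nnls_baseline:
            pred = nnls_deconvolve(test_bulk, type_centroids(atlas))
            write_matrix_csv(out / "nnls.predictions.csv", pred,
                             atlas.type_names)
            rep = evaluate_predictions(test_props, pred, atlas.type_names)
            reports["nnls"] = rep.to_dict()
            rmse_by_method["nnls"] = rep.per_sample_rmse

        paired = []
        methods = list(rmse_by_method)
        for i, a in enumerate(methods):
            for b in methods[i + 1:]:
                paired.append(paired_rmse_ttest(
                    rmse_by_method[a], rmse_by_method[b], a, b).to_dict())

        report = {
            "methods": reports,
            "paired_tests": paired,
            "type_names": atlas.type_names,
            "provenance": {
                "package_version": __version__,
                "config": json.loads(config.model_dump_json()),
                "sub_seeds": {"reference": seed_ref, "simulation": seed_sim,
                              "training": seed_train, "inference": seed_infer},
            },
        }
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
        log_event("done", seconds=round(time.time() - t0, 1))
        return report
    except Exception as exc:
        log_event("failed", error=str(exc))
        raise
    finally:
        events.close()
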