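"""Shared fixtures.

``e2e`` is the expensive one: the reduced-scale end-to-end study (separable
synthetic reference, 1000/100 pseudo-bulk samples, DiffFormer and DiffMLP
trained identically, NNLS baseline) used by the trainer tests and the
acceptance suite.  It is session-scoped so the training cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from diffdecon.diffusion import make_schedule
from diffdecon.evaluate import evaluate_predictions, nnls_deconvolve
from diffdecon.preprocess import PreprocessConfig, build_atlas
from diffdecon.pseudobulk import SimulationConfig, dataset_arrays, generate_dataset
from diffdecon.synthetic import SynthRefConfig, simulate_reference, type_centroids
from diffdecon.train import TrainingConfig, infer_proportions, train_model


@pytest.fixture(scope="session")
def tiny_raw():
    """Small separable reference: 3 types x 40 cells, 60 genes."""
    return simulate_reference(SynthRefConfig(
        n_types=3, n_genes=60, cells_per_type=40, n_markers_per_type=8,
        marker_fold=15.0, base_mean=3.0, seed=7))


@pytest.fixture(scope="session")
def tiny_atlas(tiny_raw):
    # windows widened for the 60-gene fixture (CP10K means scale as 1/G)
    return build_atlas(tiny_raw, PreprocessConfig(
        min_genes=5, max_genes=100, min_mean=0.0, max_mean=8.0))


@pytest.fixture(scope="session")
def schedule200():
    return make_schedule(T=200)


@pytest.fixture(scope="session")
def e2e(schedule200):
    """Reduced end-to-end study: train both denoisers on separable data.

    Conditions: K=5 types, 300 genes, 20x marker over-expression; 1000
    training and 100 test pseudo-bulk samples; T=200 diffusion steps; 50
    epochs at batch 64 on CPU.
    """
    raw = simulate_reference(SynthRefConfig(
        n_types=5, n_genes=300, cells_per_type=100, marker_fold=20.0, seed=11))
    atlas = build_atlas(raw, PreprocessConfig(min_genes=50, max_genes=300))
    train, test = generate_dataset(
        atlas, SimulationConfig(n_train=1000, n_test=100, seed=12))
    train_bulk, train_props = dataset_arrays(train)
    test_bulk, test_props = dataset_arrays(test)
    cfg = TrainingConfig(epochs=50, early_stop_patience=20, seed=42)

    out = {
        "atlas": atlas,
        "train_bulk": train_bulk, "train_props": train_props,
        "test_bulk": test_bulk, "test_props": test_props,
        "config": cfg, "schedule": schedule200,
    }
    for kind in ("diffformer", "diffmlp"):
        model, trace = train_model(kind, train_bulk, train_props, cfg,
                                   schedule200)
        pred = infer_proportions(model, test_bulk, schedule200, seed=99)
        out[kind] = {
            "model": model, "trace": trace, "pred": pred,
            "report": evaluate_predictions(test_props, pred, atlas.type_names),
        }
    nnls_pred = nnls_deconvolve(test_bulk, type_centroids(atlas))
    out["nnls"] = {
        "pred": nnls_pred,
        "report": evaluate_predictions(test_props, nnls_pred, atlas.type_names),
    }
    return out
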