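"""Readers and writers for the formats the pipeline touches.

Reference input follows the 10x v2 on-disk dialect: a matrix-market sparse
counts file (genes x cells, 1-based indices) plus ``genes.tsv`` and
``barcodes.tsv``, with cell-type annotations as a two-column
(barcode, type) TSV.  A dense TSV fallback covers small hand-made matrices.
Processed artifacts (atlas, pseudo-bulk dataset, model checkpoint) are HDF5
containers written with h5py; bulk profiles and predictions travel as CSV
with a type-name/gene-id header.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .models import (Module, conditioning_stats, config_to_dict,
                     denoiser_from_dict, set_conditioning_stats)
from .preprocess import RawCountsMatrix, ReferenceAtlas
from .pseudobulk import PseudoBulkSample

__all__ = [
    "read_10x_mtx", "write_10x_mtx", "read_dense_tsv", "read_annotations",
    "save_atlas", "load_atlas", "save_dataset", "load_dataset",
    "save_checkpoint", "load_checkpoint", "read_bulk_csv", "write_matrix_csv",
]


def _str_list(values) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in values]


# ---------------------------------------------------------------- reference
def read_10x_mtx(directory: str | Path) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a matrix.mtx + genes.tsv + barcodes.tsv triplet.

    Returns (counts cells x genes, gene_ids, barcodes).  The .mtx stores
    genes x cells per the 10x convention, so the matrix is transposed here.
    """
    directory = Path(directory)
    mat = sio.mmread(directory / "matrix.mtx").tocsr().T.tocsr()
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)
    return mat, genes.iloc[:, 0].astype(str).tolist(), \
        barcodes.iloc[:, 0].astype(str).tolist()


def write_10x_mtx(directory: str | Path, counts, gene_ids: list[str],
                  barcodes: list[str], cell_types: list[str] | None = None
                  ) -> None:
    """Write the triplet (and optionally annotations.tsv) for ``counts``
    given cells x genes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts).T   # stored genes x cells
    sio.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.DataFrame({0: gene_ids, 1: gene_ids}).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({0: barcodes}).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False)
    if cell_types is not None:
        pd.DataFrame({0: barcodes, 1: cell_types}).to_csv(
            directory / "annotations.tsv", sep="\t", header=False, index=False)


def read_dense_tsv(path: str | Path, orientation: str = "cells_by_genes"
                   ) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense TSV fallback with gene ids in the header or index.

    Returns (counts cells x genes, gene_ids, cell_ids).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_by_cells":
        df = df.T
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df.to_numpy(dtype=np.float64), list(df.columns.astype(str)), \
        list(df.index.astype(str))


def read_annotations(path: str | Path) -> dict[str, str]:
    """Two-column (barcode, cell type) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation TSV needs two columns: barcode, type")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_reference(directory: str | Path) -> RawCountsMatrix:
    """Read a 10x triplet plus annotations.tsv into a RawCountsMatrix."""
    directory = Path(directory)
    counts, gene_ids, barcodes = read_10x_mtx(directory)
    ann = read_annotations(directory / "annotations.tsv")
    missing = [b for b in barcodes if b not in ann]
    if missing:
        raise ValueError(f"{len(missing)} barcodes lack annotations "
                         f"(first: {missing[:3]})")
    return RawCountsMatrix(counts=counts, gene_ids=gene_ids,
                           cell_types=[ann[b] for b in barcodes])


# -------------------------------------------------------------------- atlas
def save_atlas(path: str | Path, atlas: ReferenceAtlas) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lognorm", data=atlas.lognorm)
        f.create_dataset("hvg_ids", data=np.array(atlas.hvg_ids, dtype="S"))
        f.create_dataset("cell_types", data=np.array(atlas.cell_types, dtype="S"))
        f.create_dataset("type_names", data=np.array(atlas.type_names, dtype="S"))


def load_atlas(path: str | Path) -> ReferenceAtlas:
    with h5py.File(path, "r") as f:
        return ReferenceAtlas(
            lognorm=f["lognorm"][()],
            hvg_ids=_str_list(f["hvg_ids"][()]),
            cell_types=_str_list(f["cell_types"][()]),
            type_names=_str_list(f["type_names"][()]),
        )


# ------------------------------------------------------------------ dataset
def save_dataset(path: str | Path, train: list[PseudoBulkSample],
                 test: list[PseudoBulkSample], type_names: list[str],
                 hvg_ids: list[str], sim_config: dict) -> None:
    from .pseudobulk import dataset_arrays
    with h5py.File(path, "w") as f:
        for split, samples in (("train", train), ("test", test)):
            bulk, props = dataset_arrays(samples)
            grp = f.create_group(split)
            grp.create_dataset("bulk", data=bulk)
            grp.create_dataset("proportions", data=props)
            grp.attrs["n_cells"] = samples[0].n_cells if samples else 0
        f.create_dataset("type_names", data=np.array(type_names, dtype="S"))
        f.create_dataset("hvg_ids", data=np.array(hvg_ids, dtype="S"))
        f.attrs["sim_config"] = json.dumps(sim_config, sort_keys=True)


def load_dataset(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "train_bulk": f["train/bulk"][()],
            "train_props": f["train/proportions"][()],
            "test_bulk": f["test/bulk"][()],
            "test_props": f["test/proportions"][()],
            "type_names": _str_list(f["type_names"][()]),
            "hvg_ids": _str_list(f["hvg_ids"][()]),
            "sim_config": json.loads(f.attrs["sim_config"]),
        }


def export_dataset_csv(path_prefix: str | Path, bulk: np.ndarray,
                       props: np.ndarray, type_names: list[str],
                       hvg_ids: list[str]) -> None:
    """CSV export for interoperability with external deconvolution tools."""
    prefix = Path(path_prefix)
    write_matrix_csv(prefix.with_suffix(".bulk.csv"), bulk, hvg_ids)
    write_matrix_csv(prefix.with_suffix(".proportions.csv"), props, type_names)


# --------------------------------------------------------------- checkpoint
def save_checkpoint(path: str | Path, model: Module, type_names: list[str],
                    hvg_ids: list[str], training_seed: int,
                    extra: dict | None = None) -> None:
    meta = {
        "model": config_to_dict(model),
        "type_names": list(type_names),
        "hvg_ids": list(hvg_ids),
        "training_seed": int(training_seed),
    }
    if extra:
        meta["extra"] = extra
    cond_mean, cond_std = conditioning_stats(model)
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for i, arr in enumerate(model.state_arrays()):
            grp.create_dataset(f"p{i:04d}", data=arr)
        buf = f.create_group("buffers")
        buf.create_dataset("cond_mean", data=cond_mean)
        buf.create_dataset("cond_std", data=cond_std)
        f.attrs["meta"] = json.dumps(meta, sort_keys=True)


def load_checkpoint(path: str | Path) -> tuple[Module, dict]:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        model = denoiser_from_dict(meta["model"])
        arrays = [f["params"][k][()] for k in sorted(f["params"].keys())]
        cond_mean = f["buffers/cond_mean"][()]
        cond_std = f["buffers/cond_std"][()]
    model.load_state_arrays(arrays)
    set_conditioning_stats(model, cond_mean, cond_std)
    model.eval()
    return model, meta


# --------------------------------------------------------------------- CSVs
def read_bulk_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Samples x genes CSV/TSV with a gene-id header column set."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.columns.astype(str))


def write_matrix_csv(path: str | Path, matrix: np.ndarray,
                     columns: list[str]) -> None:
    pd.DataFrame(matrix, columns=columns).to_csv(
        path, index_label="sample")


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.columns.astype(str))
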