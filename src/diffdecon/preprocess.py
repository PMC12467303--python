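"""Single-cell reference preprocessing: QC, normalization, HVG selection.

The reference pipeline mirrors the standard scanpy recipe: cells are filtered
on detected-gene count and mitochondrial fraction, genes on prevalence;
counts are normalized to counts-per-10k and log1p-transformed; the top
highly variable genes are selected by mean-binned normalized dispersion.
The result is a :class:`ReferenceAtlas`, the processed, HVG-restricted,
cell-type-labelled matrix every downstream stage (pseudo-bulk simulation,
conditioning, the NNLS baseline) consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "RawCountsMatrix",
    "ReferenceAtlas",
    "PreprocessConfig",
    "qc_filter",
    "normalize_cp10k_log1p",
    "select_hvgs",
    "build_atlas",
]


def _to_dense(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray(counts.todense(), dtype=np.float64)
    return np.asarray(counts, dtype=np.float64)


@dataclass
class RawCountsMatrix:
    """Raw integer counts with gene ids and per-cell type labels.

    ``counts`` may be dense or scipy-sparse, cells x genes.  ``mito_flags``
    defaults to a "MT-"/"mt-" gene-name prefix convention.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_types: list[str]
    mito_flags: np.ndarray | None = None

    def __post_init__(self):
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns")
        if len(self.cell_types) != n_cells:
            raise ValueError(
                f"{len(self.cell_types)} cell-type labels for {n_cells} rows")
        mn = self.counts.min() if not sp.issparse(self.counts) else self.counts.min()
        if mn < 0:
            raise ValueError("counts must be non-negative")
        if self.mito_flags is None:
            self.mito_flags = np.array(
                [g.upper().startswith("MT-") for g in self.gene_ids], dtype=bool)
        else:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
            if self.mito_flags.size != n_genes:
                raise ValueError("mito_flags length must equal n_genes")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ReferenceAtlas:
    """Processed log-normalized reference restricted to the selected HVGs."""

    lognorm: np.ndarray          # cells x G_hvg
    hvg_ids: list[str]
    cell_types: list[str]
    type_names: list[str]        # sorted unique types; fixes the K-indexing

    def __post_init__(self):
        if self.lognorm.shape != (len(self.cell_types), len(self.hvg_ids)):
            raise ValueError("lognorm shape inconsistent with metadata")
        if np.any(self.lognorm < 0):
            raise ValueError("lognorm must be non-negative")
        missing = set(self.cell_types) - set(self.type_names)
        if missing:
            raise ValueError(f"cell types not in type_names: {sorted(missing)}")
        if len(self.type_names) < 2:
            raise ValueError("a reference needs at least 2 cell types")

    @property
    def K(self) -> int:
        return len(self.type_names)

    @property
    def G(self) -> int:
        return len(self.hvg_ids)

    def type_indices(self) -> dict[str, np.ndarray]:
        ct = np.asarray(self.cell_types)
        return {t: np.flatnonzero(ct == t) for t in self.type_names}


@dataclass(frozen=True)
class PreprocessConfig:
    min_genes: int = 200
    max_genes: int = 5000
    max_mito_frac: float = 0.20
    min_cells_per_gene: int = 3
    n_top_hvgs: int = 2000
    min_mean: float = 0.0125
    max_mean: float = 3.0
    min_disp: float = 0.5
    n_bins: int = 20
    allow_type_loss: bool = False   # error if QC removes a whole cell type


def qc_filter(raw: RawCountsMatrix, min_genes: int = 200, max_genes: int = 5000,
              max_mito_frac: float = 0.20,
              min_cells_per_gene: int = 3) -> RawCountsMatrix:
    """Filter low-quality cells, then low-prevalence genes.

    A cell is kept when its detected-gene count lies in
    ``[min_genes, max_genes]`` and its mitochondrial count fraction is at
    most ``max_mito_frac``.  Genes expressed in fewer than
    ``min_cells_per_gene`` retained cells are then dropped (prevalence is
    computed on the retained cells, which is why the cell filter runs first).
    """
    if raw.n_cells == 0:
        raise ValueError("empty input matrix")
    X = raw.counts.tocsr() if sp.issparse(raw.counts) else np.asarray(raw.counts)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, raw.mito_flags].sum(axis=1)).ravel() \
        if raw.mito_flags.any() else np.zeros(raw.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 1.0)
    keep_cells = ((detected >= min_genes) & (detected <= max_genes)
                  & (mito_frac <= max_mito_frac))
    if not keep_cells.any():
        raise ValueError("empty after QC: every cell was filtered out")
    Xc = X[keep_cells]
    prevalence = np.asarray((Xc > 0).sum(axis=0)).ravel()
    keep_genes = prevalence >= min_cells_per_gene
    return RawCountsMatrix(
        counts=Xc[:, keep_genes],
        gene_ids=[g for g, k in zip(raw.gene_ids, keep_genes) if k],
        cell_types=[t for t, k in zip(raw.cell_types, keep_cells) if k],
        mito_flags=raw.mito_flags[keep_genes],
    )


def normalize_cp10k_log1p(raw: RawCountsMatrix) -> np.ndarray:
    """Scale each cell to 10,000 total counts, then log1p. Returns dense."""
    X = _to_dense(raw.counts)
    totals = X.sum(axis=1)
    zero_rows = np.flatnonzero(totals == 0)
    if zero_rows.size:
        raise ValueError(
            f"cannot normalize: zero total counts in cell row(s) {zero_rows[:5].tolist()}")
    return np.log1p(X / totals[:, None] * 1e4)


def select_hvgs(lognorm: np.ndarray, gene_ids: list[str], n_top: int = 2000,
                min_mean: float = 0.0125, max_mean: float = 3.0,
                min_disp: float = 0.5, n_bins: int = 20) -> list[str]:
    """Dispersion-based highly-variable-gene selection.

    Delegates to scanpy's ``highly_variable_genes`` (seurat flavor: per-gene
    mean and dispersion = variance/mean on the expm1 scale, dispersions
    z-scored within mean bins), then ranks the passing genes by normalized
    dispersion with gene-id lexicographic tie-breaking so the returned order
    is deterministic.  If fewer than ``n_top`` genes pass the mean/dispersion
    window, all passers are returned with a warning.
    """
    adata = ad.AnnData(X=np.asarray(lognorm, dtype=np.float64))
    adata.var_names = list(gene_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, min_mean=min_mean, max_mean=max_mean,
                                    min_disp=min_disp, n_bins=n_bins,
                                    flavor="seurat")
    passing = adata.var[adata.var["highly_variable"]]
    if len(passing) < n_top:
        logger.warning("only %d genes pass the HVG window (requested %d)",
                       len(passing), n_top)
    order = sorted(passing.index,
                   key=lambda g: (-passing.loc[g, "dispersions_norm"], g))
    return list(order[:n_top])


def build_atlas(raw: RawCountsMatrix,
                config: PreprocessConfig = PreprocessConfig()) -> ReferenceAtlas:
    """QC -> CP10K/log1p -> HVG selection -> column subset, in fixed order."""
    types_before = set(raw.cell_types)
    filtered = qc_filter(raw, config.min_genes, config.max_genes,
                         config.max_mito_frac, config.min_cells_per_gene)
    types_after = set(filtered.cell_types)
    lost = types_before - types_after
    if lost and not config.allow_type_loss:
        raise ValueError(
            f"QC removed every cell of type(s) {sorted(lost)}; "
            "set allow_type_loss=True to proceed with reduced K")
    lognorm = normalize_cp10k_log1p(filtered)
    hvg_ids = select_hvgs(lognorm, filtered.gene_ids, config.n_top_hvgs,
                          config.min_mean, config.max_mean, config.min_disp,
                          config.n_bins)
    col_index = {g: i for i, g in enumerate(filtered.gene_ids)}
    cols = np.array([col_index[g] for g in hvg_ids], dtype=np.int64)
    return ReferenceAtlas(
        lognorm=lognorm[:, cols],
        hvg_ids=hvg_ids,
        cell_types=list(filtered.cell_types),
        type_names=sorted(types_after),
    )
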