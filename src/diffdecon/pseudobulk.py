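"""Pseudo-bulk simulation: Dirichlet proportions, cell mixing, datasets.

A pseudo-bulk sample is built by drawing a cell-type proportion vector from a
symmetric Dirichlet (alpha = 1, i.e. uniform on the simplex), converting it
to per-type cell counts with one multinomial draw over a fixed total of 2000
cells, sampling that many cells with replacement from each type, and
averaging their log-normalized profiles.  The recorded ground truth is the
*realized* sampled fraction (multinomial counts / n_cells), since that is
what the averaged profile actually contains; the latent Dirichlet draw is
available behind ``truth="latent"`` for sensitivity analyses.

One seeded generator drives proportions and cell sampling in a documented
order (proportion draw, multinomial, per-type index draws in ``type_names``
order), so a single seed fixes the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ReferenceAtlas

__all__ = ["SimulationConfig", "PseudoBulkSample", "sample_proportions",
           "compose_pseudobulk", "generate_dataset", "dataset_arrays"]


@dataclass(frozen=True)
class SimulationConfig:
    alpha: float = 1.0
    n_cells: int = 2000
    n_train: int = 5000
    n_test: int = 500
    seed: int = 0
    truth: str = "realized"   # or "latent"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if min(self.n_cells, self.n_train, self.n_test) < 1:
            raise ValueError("n_cells, n_train and n_test must be positive")
        if self.truth not in ("realized", "latent"):
            raise ValueError("truth must be 'realized' or 'latent'")


@dataclass
class PseudoBulkSample:
    bulk: np.ndarray      # length G_hvg, mean lognorm expression
    p_true: np.ndarray    # length K, simplex-valid
    n_cells: int

    def __post_init__(self):
        if np.any(self.bulk < 0):
            raise ValueError("bulk expression must be non-negative")
        if np.any(self.p_true < 0) or abs(self.p_true.sum() - 1.0) > 1e-9:
            raise ValueError("p_true must be a proportion vector")


def sample_proportions(K: int, alpha: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One draw from the symmetric Dirichlet(alpha) over K types."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K == 1:
        return np.ones(1)
    return rng.dirichlet(np.full(K, alpha))


def compose_pseudobulk(atlas: ReferenceAtlas, p: np.ndarray, n_cells: int,
                       rng: np.random.Generator,
                       truth: str = "realized") -> PseudoBulkSample:
    """Mix reference cells according to ``p`` into one pseudo-bulk profile."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (atlas.K,):
        raise ValueError(f"p has length {p.size}, atlas has K={atlas.K}")
    idx = atlas.type_indices()
    for t, weight in zip(atlas.type_names, p):
        if weight > 0 and idx[t].size == 0:
            raise ValueError(f"type {t!r} has positive weight but no reference cells")
    counts = rng.multinomial(n_cells, p)
    rows = []
    for t, c in zip(atlas.type_names, counts):
        if c > 0:
            rows.append(idx[t][rng.integers(0, idx[t].size, size=c)])
    chosen = np.concatenate(rows)
    bulk = atlas.lognorm[chosen].mean(axis=0)
    p_true = counts / n_cells if truth == "realized" else p
    return PseudoBulkSample(bulk=bulk, p_true=p_true, n_cells=n_cells)


def generate_dataset(atlas: ReferenceAtlas, sim: SimulationConfig
                     ) -> tuple[list[PseudoBulkSample], list[PseudoBulkSample]]:
    """Seeded train/test pseudo-bulk sets (disjoint draws from one stream)."""
    rng = np.random.Generator(np.random.PCG64(sim.seed))
    samples = []
    for _ in range(sim.n_train + sim.n_test):
        p = sample_proportions(atlas.K, sim.alpha, rng)
        samples.append(compose_pseudobulk(atlas, p, sim.n_cells, rng, sim.truth))
    return samples[:sim.n_train], samples[sim.n_train:]


def dataset_arrays(samples: list[PseudoBulkSample]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack a sample list into (bulk N x G, proportions N x K) arrays."""
    if not samples:
        return np.zeros((0, 0)), np.zeros((0, 0))
    return (np.stack([s.bulk for s in samples]),
            np.stack([s.p_true for s in samples]))
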