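"""Evaluation suite: RMSE, per-type and overall PCC, paired tests, NNLS.

Per-sample RMSE is the root mean squared error over a sample's K proportion
entries.  Per-type PCC correlates true and predicted fractions of one cell
type across samples; a type whose predictions (or truths) are constant has
undefined correlation and is reported as NaN with its name listed in
``failed_types`` — a diagnostic of model collapse, not an error.  Overall
PCC flattens both N x K matrices row-major into single vectors and
correlates those.  Method comparison uses two-tailed paired t-tests on
per-sample RMSE with Cohen's d = mean(diff)/sd(diff) (sample sd, N-1);
negative d means the first method has the lower error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

__all__ = ["EvalReport", "PairedTestResult", "per_sample_rmse", "per_type_pcc",
           "overall_pcc", "paired_rmse_ttest", "stability_summary",
           "nnls_deconvolve", "evaluate_predictions"]


@dataclass
class EvalReport:
    per_sample_rmse: np.ndarray
    per_type_pcc: np.ndarray          # NaN marks an undefined correlation
    overall_pcc: float
    overall_rmse: float               # mean of per-sample RMSE
    rmse_median: float
    rmse_iqr: float
    failed_types: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_sample_rmse"] = [float(v) for v in self.per_sample_rmse]
        d["per_type_pcc"] = [None if np.isnan(v) else float(v)
                             for v in self.per_type_pcc]
        return d


@dataclass
class PairedTestResult:
    method_a: str
    method_b: str
    mean_diff: float       # mean(rmse_a - rmse_b); negative => a better
    t_stat: float          # NaN when differences have zero variance
    p_value: float
    cohens_d: float
    n: int

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in asdict(self).items()}


def _check_pair(p_true: np.ndarray, p_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_true = np.asarray(p_true, dtype=np.float64)
    p_pred = np.asarray(p_pred, dtype=np.float64)
    if p_true.shape != p_pred.shape or p_true.ndim != 2:
        raise ValueError(f"shape mismatch: {p_true.shape} vs {p_pred.shape}")
    return p_true, p_pred


def per_sample_rmse(p_true: np.ndarray, p_pred: np.ndarray) -> np.ndarray:
    p_true, p_pred = _check_pair(p_true, p_pred)
    return np.sqrt(np.mean((p_true - p_pred) ** 2, axis=1))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with explicit NaN for zero-variance input."""
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def per_type_pcc(p_true: np.ndarray, p_pred: np.ndarray) -> np.ndarray:
    p_true, p_pred = _check_pair(p_true, p_pred)
    if p_true.shape[0] < 2:
        raise ValueError("need at least 2 samples for per-type correlation")
    return np.array([_pearson(p_true[:, k], p_pred[:, k])
                     for k in range(p_true.shape[1])])


def overall_pcc(p_true: np.ndarray, p_pred: np.ndarray) -> float:
    """Pearson r between the row-major flattened proportion matrices."""
    p_true, p_pred = _check_pair(p_true, p_pred)
    if p_true.size < 2:
        raise ValueError("need at least 2 values")
    return _pearson(p_true.ravel(order="C"), p_pred.ravel(order="C"))


def paired_rmse_ttest(rmse_a: np.ndarray, rmse_b: np.ndarray,
                      name_a: str = "a", name_b: str = "b") -> PairedTestResult:
    rmse_a = np.asarray(rmse_a, dtype=np.float64)
    rmse_b = np.asarray(rmse_b, dtype=np.float64)
    if rmse_a.shape != rmse_b.shape or rmse_a.ndim != 1:
        raise ValueError("paired test needs equal-length 1-D error vectors")
    n = rmse_a.size
    if n < 2:
        raise ValueError("need at least 2 paired samples")
    diff = rmse_a - rmse_b
    sd = diff.std(ddof=1)
    # constant differences (up to float cancellation) have no defined t
    if sd <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        if np.allclose(diff, 0.0):
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p, d = np.nan, np.nan, np.nan
    else:
        res = stats.ttest_rel(rmse_a, rmse_b)
        t, p = float(res.statistic), float(res.pvalue)
        d = float(diff.mean() / sd)
    return PairedTestResult(method_a=name_a, method_b=name_b,
                            mean_diff=float(diff.mean()), t_stat=t,
                            p_value=p, cohens_d=d, n=n)


def stability_summary(per_sample: np.ndarray) -> dict[str, float]:
    """Median, quartiles and IQR (linear-interpolation quantiles)."""
    per_sample = np.asarray(per_sample, dtype=np.float64)
    if per_sample.size < 4:
        raise ValueError("need at least 4 samples for a quartile summary")
    q1, med, q3 = np.percentile(per_sample, [25, 50, 75], method="linear")
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "iqr": float(q3 - q1)}


def nnls_deconvolve(bulk: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Non-negative least squares against type centroids, sum-to-one scaled.

    The minimal linear baseline: solves ``min ||centroids^T w - bulk||`` with
    ``w >= 0`` and renormalizes.  An all-zero solution falls back to uniform.
    """
    bulk = np.asarray(bulk, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    squeeze = bulk.ndim == 1
    bulk = np.atleast_2d(bulk)
    K = centroids.shape[0]
    out = np.zeros((bulk.shape[0], K))
    for i, row in enumerate(bulk):
        w, _ = optimize.nnls(centroids.T, row)
        s = w.sum()
        out[i] = w / s if s > 0 else np.full(K, 1.0 / K)
    return out[0] if squeeze else out


def evaluate_predictions(p_true: np.ndarray, p_pred: np.ndarray,
                         type_names: list[str] | None = None) -> EvalReport:
    """Assemble the full report for one method's predictions."""
    rmse = per_sample_rmse(p_true, p_pred)
    pcc = per_type_pcc(p_true, p_pred)
    summ = stability_summary(rmse) if rmse.size >= 4 else \
        {"median": float(np.median(rmse)), "iqr": np.nan}
    if type_names is None:
        type_names = [f"type_{k}" for k in range(p_true.shape[1])]
    failed = [t for t, v in zip(type_names, pcc) if np.isnan(v)]
    return EvalReport(
        per_sample_rmse=rmse,
        per_type_pcc=pcc,
        overall_pcc=overall_pcc(p_true, p_pred),
        overall_rmse=float(rmse.mean()),
        rmse_median=summ["median"],
        rmse_iqr=summ["iqr"],
        failed_types=failed,
    )
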