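"""Unsupervised sample screening: PCA on autoscaled bucket tables and
Hotelling-T² outlier exclusion at the 95% level.

Before any supervised model, each compartment's bucket table is inspected by
principal component analysis on unit-variance-scaled data. A sample whose
T² statistic in the retained score space exceeds the F-distribution-based
critical value (the convention of SIMCA-family chemometrics software) falls
outside the 95% confidence ellipse and is excluded from subsequent models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

logger = logging.getLogger("metadigest")


def autoscale_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to unit variance (n-1 denominator).
    Constant columns get scale 1 and are flagged.
    Returns (scaled, means, scales, constant_mask)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    const = sds == 0.0
    scales = np.where(const, 1.0, sds)
    return (X - means) / scales, means, scales, const


@dataclass
class PCAModel:
    """PCA of an autoscaled matrix: loadings are orthonormal eigenvectors of
    the scaled covariance; eigenvalues are score variances (n-1 denominator)."""

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray        # p x A, orthonormal columns
    scores: np.ndarray          # n x A
    eigenvalues: np.ndarray     # all min(n-1, p) eigenvalues, non-increasing
    n_components: int
    sample_ids: list[str] | None = None
    constant_columns: np.ndarray | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues[: self.n_components] / self.eigenvalues.sum()


def fit_pca(X, A: int = 2, sample_ids: list[str] | None = None) -> PCAModel:
    """Fit PCA with A components on the unit-variance-scaled matrix via SVD.

    X may be an array or anything with ``.values``/``.index`` (a DataFrame or
    :class:`~metadigest.io.BucketTable` data frame).
    """
    if hasattr(X, "data") and isinstance(getattr(X, "data"), pd.DataFrame):
        sample_ids = sample_ids or list(X.data.index)   # BucketTable
        X = X.data.values
    elif isinstance(X, pd.DataFrame):
        sample_ids = sample_ids or list(X.index)
        X = X.values
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"PCA needs at least 3 samples, got {n}")
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} must lie in [1, min(n-1, p)={min(n - 1, p)}]")
    Xs, means, scales, const = autoscale_matrix(X)
    if const.any():
        logger.warning("PCA: %d constant column(s) scaled by 1", int(const.sum()))
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s ** 2 / (n - 1)
    loadings = Vt[:A].T
    scores = Xs @ loadings
    return PCAModel(means=means, scales=scales, loadings=loadings,
                    scores=scores, eigenvalues=eig, n_components=A,
                    sample_ids=sample_ids, constant_columns=const)


@dataclass
class OutlierReport:
    t2: pd.Series               # per-sample Hotelling T²
    critical_value: float
    alpha: float
    n_components: int
    excluded: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T2": self.t2,
            "excluded": [s in set(self.excluded) for s in self.t2.index],
        })

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.12g")


def hotelling_screen(model: PCAModel, alpha: float = 0.05) -> OutlierReport:
    """Hotelling-T² outlier test in the retained PCA score space.

    T²_i = sum_a t_ia² / λ_a, compared against the 1-alpha critical value
    A(N-1)(N+1) / (N(N-A)) * F_{1-alpha}(A, N-A). Samples above the limit lie
    outside the confidence ellipse and are reported as outliers.
    """
    A = model.n_components
    n = model.scores.shape[0]
    if n <= A:
        raise ValueError(f"need more samples ({n}) than components ({A})")
    lam = model.eigenvalues[:A]
    if np.any(lam <= 0):
        raise ValueError("non-positive eigenvalue among retained components")
    t2 = (model.scores ** 2 / lam).sum(axis=1)
    crit = (A * (n - 1) * (n + 1)) / (n * (n - A)) * f_dist.ppf(1 - alpha, A, n - A)
    ids = model.sample_ids or [str(i) for i in range(n)]
    t2_series = pd.Series(t2, index=pd.Index(ids, name="sample_id"), name="T2")
    excluded = [i for i, v in zip(ids, t2) if v > crit]
    if excluded:
        logger.info("Hotelling screen (A=%d, alpha=%.3g): excluded %d/%d "
                    "sample(s): %s", A, alpha, len(excluded), n, excluded)
    return OutlierReport(t2=t2_series, critical_value=float(crit), alpha=alpha,
                         n_components=A, excluded=excluded)


def screen_bucket_table(table, A: int = 2, alpha: float = 0.05):
    """Convenience: fit PCA on a bucket table, screen, and return the
    (screened table, report) pair."""
    model = fit_pca(table.data, A=A)
    report = hotelling_screen(model, alpha=alpha)
    return table.drop_samples(report.excluded), report
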