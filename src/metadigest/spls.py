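"""Canonical-mode sparse PLS between a bucket table (X) and the trait block
(Y), with exact-cardinality LASSO loading selection, per-block explained
variance, and first-component similarity matrices.

Unlike the predictive PLS regression, the canonical model treats the two
blocks symmetrically: each component maximizes the covariance between an
X score and a Y score, each block is deflated by its own score, and a
soft-thresholding (LASSO-style) step zeroes all but a fixed number of X
loadings. The study convention keeps one-quarter of the metabolomic
variables per component and all traits (no Y selection).

Association between an individual bucket and an individual trait is then
summarized by the similarity score
``sim(j, k) = Σ_h cor(X_j, ξ_h) · cor(Y_k, ω_h)`` computed on the original
scaled blocks; with a single component every entry is a product of two
correlations and lies in [−1, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screening import autoscale_matrix

logger = logging.getLogger("metadigest")

SPLS_TOL = 1e-9
SPLS_MAX_ITER = 500


class ConvergenceError(RuntimeError):
    pass


def keep_quarter(p: int) -> int:
    """The variable-selection cardinality rule: keep one-quarter of the
    block's variables, rounded to the nearest integer with .5 rounding up
    (191 -> 48, 160 -> 40, 64 -> 16); never below 1."""
    if p < 4:
        warnings.warn(f"only {p} variables; keeping 1", stacklevel=2)
        return 1
    return max(1, int(math.floor(p / 4.0 + 0.5)))


def _sparse_unit(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``a`` so that exactly ``keep`` entries survive, then
    normalize to unit length. The threshold λ is the (keep+1)-th largest
    |entry| (0 when keep >= p); magnitude ties are broken toward the lower
    variable index."""
    p = a.size
    if keep >= p:
        out = a.copy()
    else:
        order = np.lexsort((np.arange(p), -np.abs(a)))
        kept = order[:keep]
        lam = abs(float(a[order[keep]]))
        out = np.zeros(p)
        shrunk = np.abs(a[kept]) - lam
        # an exact magnitude tie at the threshold would shrink a kept entry
        # to zero; keep it at a vanishing magnitude to preserve cardinality
        tied = (shrunk <= 0) & (np.abs(a[kept]) > 0)
        floor = (shrunk[~tied].min() if (~tied).any() else 1.0) * 1e-9
        shrunk[tied] = floor
        out[kept] = np.sign(a[kept]) * shrunk
    norm = float(np.linalg.norm(out))
    if norm == 0.0:
        raise ValueError("degenerate loading vector (all entries zero)")
    return out / norm


@dataclass
class SPLSModel:
    n_components: int
    keep_x: int
    keep_y: int
    x_loadings: np.ndarray        # U, p x H, unit sparse columns
    y_loadings: np.ndarray        # V, q x H, unit columns
    x_scores: np.ndarray          # ξ, n x H
    y_scores: np.ndarray          # ω, n x H
    x_scaled: np.ndarray          # original (undeflated) scaled blocks
    y_scaled: np.ndarray
    x_explained: np.ndarray       # per-component explained variance of X
    y_explained: np.ndarray
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    def selected(self, component: int = 1) -> list:
        """Names (or indices) of the X variables kept on a component."""
        u = self.x_loadings[:, component - 1]
        idx = np.flatnonzero(u)
        if self.x_names is not None:
            return [self.x_names[j] for j in idx]
        return list(idx)

    def loading_table(self) -> pd.DataFrame:
        idx = self.x_names or list(range(self.x_loadings.shape[0]))
        return pd.DataFrame(
            {f"u[{h + 1}]": self.x_loadings[:, h]
             for h in range(self.n_components)},
            index=pd.Index(idx, name="variable"))


def explained_variance(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Per-component fraction of a block's variance captured by the scores:
    the mean over the block's variables of cor²(variable, score), computed
    on the undeflated scaled block. Constant variables are excluded."""
    block = np.asarray(block, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != block.shape[0]:
        scores = scores.T
    sds = block.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        logger.warning("explained_variance: excluded %d constant variable(s)",
                       int((~keep).sum()))
    out = []
    for h in range(scores.shape[1]):
        s = scores[:, h]
        s_sd = s.std(ddof=1)
        if s_sd == 0:
            out.append(0.0)
            continue
        cors = ((block[:, keep] - block[:, keep].mean(axis=0)).T @ (s - s.mean())
                / ((block.shape[0] - 1) * sds[keep] * s_sd))
        out.append(float(np.mean(cors ** 2)))
    return np.array(out)


def fit_spls_canonical(X, Y, H: int = 2, keep_x: int | None = None,
                       keep_y: int | None = None) -> SPLSModel:
    """Fit a canonical-mode sparse PLS model.

    Per component, on the current residual blocks: M = XᵀY; v starts at the
    leading right singular vector of M; then u ← soft_threshold(Mv) and
    v ← soft_threshold(Mᵀu) alternate (each normalized, with thresholds set
    by the keep_x/keep_y order statistics) until convergence. Scores are
    ξ = Xu and ω = Yv, and each block is deflated by the regression on its
    own score (canonical mode). The component sign is fixed so that the
    largest-|entry| element of u is positive; v flips jointly so that the
    (u, v) pair keeps its orientation.
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)
    Y = np.asarray(Y.values if isinstance(Y, pd.DataFrame) else Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    keep_x = p if keep_x is None else min(keep_x, p)
    keep_y = q if keep_y is None else min(keep_y, q)
    if keep_x < 1 or keep_y < 1:
        raise ValueError("keep_x and keep_y must be at least 1")

    Xs, *_ = autoscale_matrix(X)
    Ys, *_ = autoscale_matrix(Y)
    Ex, Ey = Xs.copy(), Ys.copy()
    U = np.zeros((p, H))
    V = np.zeros((q, H))
    Tx = np.zeros((n, H))
    Ty = np.zeros((n, H))
    for h in range(H):
        M = Ex.T @ Ey
        if float(np.abs(M).max()) < 1e-14:
            raise ValueError(f"degenerate cross-covariance at component {h + 1}")
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        v = Vt[0]
        u = _sparse_unit(M @ v, keep_x)
        converged = False
        for _ in range(SPLS_MAX_ITER):
            u_old, v_old = u, v
            u = _sparse_unit(M @ v, keep_x)
            v = _sparse_unit(M.T @ u, keep_y)
            if (np.linalg.norm(u - u_old) + np.linalg.norm(v - v_old)) < SPLS_TOL:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"component {h + 1} did not converge in {SPLS_MAX_ITER} iterations")
        if u[int(np.argmax(np.abs(u)))] < 0:
            u, v = -u, -v
        xi = Ex @ u
        om = Ey @ v
        Ex = Ex - np.outer(xi, xi @ Ex) / float(xi @ xi)
        Ey = Ey - np.outer(om, om @ Ey) / float(om @ om)
        U[:, h], V[:, h], Tx[:, h], Ty[:, h] = u, v, xi, om

    return SPLSModel(n_components=H, keep_x=keep_x, keep_y=keep_y,
                     x_loadings=U, y_loadings=V, x_scores=Tx, y_scores=Ty,
                     x_scaled=Xs, y_scaled=Ys,
                     x_explained=explained_variance(Xs, Tx),
                     y_explained=explained_variance(Ys, Ty),
                     x_names=x_names, y_names=y_names)


@dataclass
class SimilarityMatrix:
    """Bucket x trait association scores from the model's score space."""

    values: pd.DataFrame
    components: tuple[int, ...]

    def write(self, path) -> None:
        df = self.values.copy()
        df.index.name = "variable"
        df.to_csv(path, sep="\t", float_format="%.12g")


def _score_correlations(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    n = block.shape[0]
    bc = block - block.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    b_sd = block.std(axis=0, ddof=1)
    s_sd = scores.std(axis=0, ddof=1)
    b_sd = np.where(b_sd == 0, 1.0, b_sd)
    s_sd = np.where(s_sd == 0, 1.0, s_sd)
    return (bc.T @ sc) / ((n - 1) * np.outer(b_sd, s_sd))


def similarity_matrix(model: SPLSModel,
                      components: tuple[int, ...] = (1,)) -> SimilarityMatrix:
    """Pairwise association scores between X variables and Y variables:
    sim(j, k) = Σ_h cor(X_j, ξ_h) · cor(Y_k, ω_h) over the requested
    components, correlations taken on the original scaled blocks. Restricted
    to the X variables selected on those components (unselected buckets have
    no loading and are not part of the association structure)."""
    for h in components:
        if not 1 <= h <= model.n_components:
            raise ValueError(f"component {h} not in model (H={model.n_components})")
    hs = [h - 1 for h in components]
    cx = _score_correlations(model.x_scaled, model.x_scores[:, hs])
    cy = _score_correlations(model.y_scaled, model.y_scores[:, hs])
    sim = cx @ cy.T
    sel = np.zeros(model.x_loadings.shape[0], dtype=bool)
    for h in hs:
        sel |= model.x_loadings[:, h] != 0
    x_names = model.x_names or [f"x{j}" for j in range(sim.shape[0])]
    y_names = model.y_names or [f"y{k}" for k in range(sim.shape[1])]
    df = pd.DataFrame(sim, index=x_names, columns=y_names).loc[
        [nm for nm, s in zip(x_names, sel) if s]]
    return SimilarityMatrix(values=df, components=tuple(components))
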