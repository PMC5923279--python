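"""NIPALS PLS regression of one trait on a bucket table, with VIP,
7-fold cross-validation, delete-a-group jackknife confidence intervals,
CV-ANOVA, and iterative variable selection.

The regression follows the chemometric workflow used to hunt spectral
biomarkers of a quantitative trait: both blocks are autoscaled, components
are extracted by NIPALS with deflation, and model quality is judged by
R²Y (goodness of fit), Q² from 7-fold cross-validation (goodness of
prediction), RMSEE/RMSECV, and a CV-ANOVA F-test on the cross-validated
residuals. Variables are then pruned iteratively: a bucket is dropped only
when its importance in the projection (VIP) is low, its jackknife confidence
interval straddles zero, AND its regression coefficient is small — until the
predictive ability Q² stops improving.

For a single response the NIPALS weight update has a closed form
(w ∝ Xᵀy on the current residuals), so each component is computed in one
pass; the iterative update only matters for multi-response PLS, which this
module does not implement.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .screening import autoscale_matrix

logger = logging.getLogger("metadigest")

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


def autoscale(X: np.ndarray):
    """Column-wise centering and unit-variance scaling; see
    :func:`metadigest.screening.autoscale_matrix`."""
    return autoscale_matrix(np.atleast_2d(np.asarray(X, dtype=float)))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted NIPALS PLS model for a single response.

    Weights W, loadings P and scores T live in the autoscaled X space;
    c holds the per-component Y loadings (scaled y regressed on each score).
    W* = W (PᵀW)⁻¹ rotates weights so that T = Xs W*; B = W* c are the
    regression coefficients in scaled space and ``coef_`` their
    back-transformed original-scale counterparts.
    """

    n_components: int
    weights: np.ndarray           # W, p x A, unit columns
    loadings: np.ndarray          # P, p x A
    scores: np.ndarray            # T, n x A
    y_loadings: np.ndarray        # c, (A,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    r2x_cum: np.ndarray           # per component, cumulative
    r2y_cum: np.ndarray
    ssy_per_component: np.ndarray  # scaled-y variance captured per component
    variable_names: list[str] | None = None

    @property
    def wstar(self) -> np.ndarray:
        return self.weights @ np.linalg.inv(self.loadings.T @ self.weights)

    @property
    def b_scaled(self) -> np.ndarray:
        return self.wstar @ self.y_loadings

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients on the original X/y scales."""
        return self.b_scaled * self.y_scale / self.x_scale

    @property
    def intercept_(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef_)

    @property
    def r2y(self) -> float:
        return float(self.r2y_cum[-1])

    def loading_display(self) -> pd.DataFrame:
        """The w*c quantities plotted on chemometric loading plots: the
        rotated X weights per component, with the Y loading appended as the
        response's coordinate."""
        ws = self.wstar
        idx = list(self.variable_names or range(ws.shape[0])) + ["__response__"]
        cols = {f"wc[{a + 1}]": np.append(ws[:, a], self.y_loadings[a])
                for a in range(self.n_components)}
        return pd.DataFrame(cols, index=idx)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        A = self.n_components if n_components is None else n_components
        if not 1 <= A <= self.n_components:
            raise ValueError(f"n_components must lie in [1, {self.n_components}]")
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        b = self.wstar[:, :A] @ self.y_loadings[:A]
        return Xs @ b * self.y_scale + self.y_mean


def fit_pls(X, y, A: int = 2,
            variable_names: list[str] | None = None) -> PLSModel:
    """Fit a PLS model with A components by NIPALS (closed-form per
    component for a single response), deflating both X and y.

    If deflation exhausts the X block before A components (rank deficiency),
    the model is truncated to the attainable number of components.
    """
    if isinstance(X, pd.DataFrame):
        variable_names = variable_names or list(X.columns)
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} values")
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} must lie in [1, min(n-1, p)={min(n - 1, p)}]")
    if np.std(y, ddof=1) == 0:
        raise ValueError("response has zero variance")

    Xs, x_mean, x_scale, const = autoscale_matrix(X)
    if const.any():
        logger.warning("PLS: %d constant column(s) scaled by 1", int(const.sum()))
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    ys = (y - y_mean) / y_sd

    ssx_total = float((Xs ** 2).sum())
    ssy_total = float((ys ** 2).sum())
    E, f_res = Xs.copy(), ys.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    c = np.zeros(A)
    r2x, r2y, ssy_comp = [], [], []
    a_eff = 0
    for a in range(A):
        w = E.T @ f_res
        nw = float(np.linalg.norm(w))
        if nw < 1e-12 * max(1.0, ssx_total):
            logger.warning("PLS: X block exhausted after %d component(s)", a)
            break
        w /= nw
        t_vec = E @ w
        tt = float(t_vec @ t_vec)
        if tt < 1e-300:
            break
        c_a = float(f_res @ t_vec) / tt
        p_vec = E.T @ t_vec / tt
        E = E - np.outer(t_vec, p_vec)
        f_res = f_res - c_a * t_vec
        W[:, a], P[:, a], T[:, a], c[a] = w, p_vec, t_vec, c_a
        r2x.append(1.0 - float((E ** 2).sum()) / ssx_total)
        r2y.append(1.0 - float((f_res ** 2).sum()) / ssy_total)
        ssy_comp.append(c_a ** 2 * tt)
        a_eff = a + 1
    if a_eff == 0:
        raise ValueError("no PLS component could be extracted (degenerate X)")
    return PLSModel(n_components=a_eff, weights=W[:, :a_eff],
                    loadings=P[:, :a_eff], scores=T[:, :a_eff],
                    y_loadings=c[:a_eff], x_mean=x_mean, x_scale=x_scale,
                    y_mean=y_mean, y_scale=y_sd,
                    r2x_cum=np.array(r2x), r2y_cum=np.array(r2y),
                    ssy_per_component=np.array(ssy_comp),
                    variable_names=variable_names)


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in the projection.

    VIP_j = sqrt( p * Σ_a SSY_a (w_aj / ‖w_a‖)² / Σ_a SSY_a ), where SSY_a is
    the response variance captured by component a. Squares average to exactly
    1 over variables, so VIP ≈ 1 is the natural "average importance" line.
    """
    W = model.weights
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0)
    ssy = model.ssy_per_component
    return np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# Cross-validation, jackknife, CV-ANOVA
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    n_components: int
    k_folds: int
    n: int
    ss_y: float                       # total SS of y about its mean
    press_per_component: np.ndarray   # out-of-fold PRESS using 1..A components
    q2: float                         # 1 - PRESS_A / SS_y
    q2_se: float                      # SE of Q2 from per-fold PRESS spread
    rmsee: float                      # sqrt(RSS / (n - 1 - A)), full-data fit
    rmsecv: float                     # sqrt(PRESS_A / n)
    oof_predictions: np.ndarray
    fold_coefficients: np.ndarray     # G x p, centered-and-scaled space
    coefficients: np.ndarray          # full-data, original scale
    coefficients_scaled: np.ndarray   # full-data, centered-and-scaled space
    jackknife_se: np.ndarray          # on the scaled coefficients
    ci_lower: np.ndarray              # scaled space; contains-zero is
    ci_upper: np.ndarray              # scale-invariant per variable
    variable_names: list[str] | None = None

    @property
    def press(self) -> float:
        return float(self.press_per_component[-1])

    def coefficient_table(self) -> pd.DataFrame:
        idx = self.variable_names or list(range(self.coefficients.size))
        return pd.DataFrame({
            "coefficient": self.coefficients,
            "coefficient_cs": self.coefficients_scaled,
            "jackknife_se": self.jackknife_se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        }, index=pd.Index(idx, name="variable"))


def venetian_folds(n: int, K: int) -> list[np.ndarray]:
    """Deterministic every-K-th fold assignment in input order
    (fold g holds the samples with index ≡ g mod K)."""
    idx = np.arange(n)
    return [idx[idx % K == g] for g in range(K)]


def cross_validate(X, y, A: int = 2, K: int = 7,
                   shuffle_seed: int | None = None,
                   ci_level: float = 0.95) -> CVReport:
    """K-fold cross-validation of a PLS model.

    Folds are assigned deterministically in input order (venetian blinds),
    independent of any global RNG; pass ``shuffle_seed`` for a seeded random
    permutation instead. Q² = 1 − PRESS/SS_y with PRESS from out-of-fold
    predictions; per-coefficient jackknife standard errors follow the
    delete-a-group formula SE_j = sqrt(((G−1)/G) Σ_g (b_jg − b̄_j)²) and the
    confidence interval is centered on the full-data coefficient with a
    t_{G−1} quantile. Coefficients, SEs and CIs are expressed in the
    full-data centered-and-scaled space, where they are comparable across
    variables regardless of bucket intensity scale (per-variable rescaling
    is positive, so whether a CI straddles zero does not depend on the
    convention); ``coefficients`` additionally holds the original-scale
    values.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2 * K:
        raise ValueError(f"need n >= 2K samples for {K}-fold CV, got n={n}")
    order = np.arange(n)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(n)
    folds = [order[f] for f in venetian_folds(n, K)]
    for g, f in enumerate(folds):
        if f.size < 2:
            raise ValueError(f"fold {g} has fewer than 2 samples")

    full = fit_pls(X, y, A, variable_names=names)
    A_eff = full.n_components
    oof = np.zeros((n, A_eff))
    fold_coefs = np.zeros((K, X.shape[1]))
    for g, test in enumerate(folds):
        train = np.setdiff1d(order, test)
        m = fit_pls(X[train], y[train], A_eff)
        for a in range(m.n_components):
            oof[test, a] = m.predict(X[test], n_components=a + 1)
        for a in range(m.n_components, A_eff):  # fold lost rank: carry last
            oof[test, a] = oof[test, m.n_components - 1]
        fold_coefs[g] = m.coef_  # original scale: comparable across folds

    ss_y = float(((y - y.mean()) ** 2).sum())
    press = ((y[:, None] - oof) ** 2).sum(axis=0)
    q2 = 1.0 - float(press[-1]) / ss_y
    resid_oof = y - oof[:, -1]
    press_g = np.array([float((resid_oof[f] ** 2).sum()) for f in folds])
    q2_se = float(np.std(press_g, ddof=1) * np.sqrt(K) / ss_y)
    resid = y - full.predict(X)
    dof = n - 1 - A_eff
    if dof <= 0:
        raise ValueError("too few samples for the RMSEE degrees of freedom")
    rmsee = math.sqrt(float((resid ** 2).sum()) / dof)
    rmsecv = math.sqrt(float(press[-1]) / n)

    # express all coefficient vectors in the full-data scaled space
    cs_factor = full.x_scale / full.y_scale
    fold_cs = fold_coefs * cs_factor
    b_cs = full.coef_ * cs_factor
    G = K
    bbar = fold_cs.mean(axis=0)
    se = np.sqrt((G - 1) / G * ((fold_cs - bbar) ** 2).sum(axis=0))
    tq = float(t_dist.ppf(0.5 + ci_level / 2, G - 1))
    return CVReport(n_components=A_eff, k_folds=K, n=n, ss_y=ss_y,
                    press_per_component=press, q2=q2, q2_se=q2_se,
                    rmsee=rmsee,
                    rmsecv=rmsecv, oof_predictions=oof[:, -1],
                    fold_coefficients=fold_cs, coefficients=full.coef_,
                    coefficients_scaled=b_cs,
                    jackknife_se=se, ci_lower=b_cs - tq * se,
                    ci_upper=b_cs + tq * se, variable_names=names)


@dataclass
class CVAnovaResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float


def cv_anova(report: CVReport, A: int | None = None) -> CVAnovaResult:
    """F-test on cross-validated residuals: compares the variation explained
    by cross-validated predictions against their residual variation,
    F = ((SS_y − PRESS)/A) / (PRESS/(n − A − 1)). If the model predicts no
    better than the mean (PRESS ≥ SS_y), F is clamped to 0 and p = 1."""
    A = report.n_components if A is None else A
    df1, df2 = A, report.n - A - 1
    if df2 <= 0:
        raise ValueError(f"non-positive residual degrees of freedom (df2={df2})")
    press, ssy = report.press, report.ss_y
    if press >= ssy:
        return CVAnovaResult(0.0, df1, df2, 1.0)
    F = ((ssy - press) / df1) / (press / df2)
    return CVAnovaResult(float(F), df1, df2, float(f_dist.sf(F, df1, df2)))


# ---------------------------------------------------------------------------
# Iterative variable selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionIteration:
    variables: list[str]
    q2: float
    q2_se: float
    r2y: float
    cv_anova_p: float
    removed: dict[str, list[str]] = field(default_factory=dict)  # var -> reasons


@dataclass
class SelectionTrace:
    iterations: list[SelectionIteration]
    best_index: int
    stopped_because: str

    @property
    def best(self) -> SelectionIteration:
        return self.iterations[self.best_index]

    def to_records(self) -> list[dict]:
        return [{
            "iteration": i,
            "n_variables": len(it.variables),
            "q2": it.q2,
            "r2y": it.r2y,
            "cv_anova_p": it.cv_anova_p,
            "removed": sorted(it.removed),
            "retained": i == self.best_index,
        } for i, it in enumerate(self.iterations)]


def iterative_selection(X: pd.DataFrame, y, A: int = 2, K: int = 7,
                        vip_threshold: float = 1.0, max_iter: int = 50,
                        q2_patience: int = 2,
                        q2_tolerance: float | None = None) -> tuple[SelectionTrace, PLSModel]:
    """Prune uninformative buckets until the model's predictive quality
    stops improving.

    Each iteration fits the model and its cross-validation on the current
    variable set, then removes every variable satisfying ALL of:
    VIP below ``vip_threshold``; jackknife CI containing 0; scaled
    |coefficient| below the median. Iteration stops when no variable
    qualifies, when Q² has failed to improve for ``q2_patience`` consecutive
    iterations, or at ``max_iter``.

    The retained model follows the cross-validation one-standard-error
    rule: the most parsimonious iteration whose Q², plus one standard error
    of its own Q² estimate (from the per-fold PRESS spread), reaches the
    maximum observed Q². Once Q² has plateaued, smaller differences are
    cross-validation noise and the sparser model is the better biomarker
    panel. Pass a float ``q2_tolerance`` to fix the margin instead
    (0 restores the strict argmax). The returned model is refit on that
    iteration's variables.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{j}" for j in range(np.shape(X)[1])])
    if X.shape[1] < 4:
        raise ValueError("iterative selection needs at least 4 variables")
    y = np.asarray(y, dtype=float).ravel()

    current = list(X.columns)
    iterations: list[SelectionIteration] = []
    best_q2 = -np.inf
    stall = 0
    reason = "max_iter reached"
    for _ in range(max_iter):
        A_it = min(A, len(current), X.shape[0] - 1)
        model = fit_pls(X[current], y, A_it)
        report = cross_validate(X[current], y, A_it, K)
        p_val = cv_anova(report).p_value
        vips = vip(model)
        it = SelectionIteration(variables=list(current), q2=report.q2,
                                q2_se=report.q2_se, r2y=model.r2y,
                                cv_anova_p=p_val)
        iterations.append(it)

        if report.q2 > best_q2 + 1e-12:
            best_q2, stall = report.q2, 0
        else:
            stall += 1
            if stall >= q2_patience:
                reason = f"Q² failed to improve for {q2_patience} iterations"
                break

        abs_b = np.abs(report.coefficients_scaled)
        med_b = float(np.median(abs_b))
        removal: dict[str, list[str]] = {}
        for j, name in enumerate(current):
            reasons = []
            if vips[j] < vip_threshold:
                reasons.append(f"VIP {vips[j]:.3f} < {vip_threshold:g}")
            if report.ci_lower[j] <= 0.0 <= report.ci_upper[j]:
                reasons.append("jackknife CI contains 0")
            if abs_b[j] < med_b:
                reasons.append("|coefficient| below median")
            if len(reasons) == 3:
                removal[name] = reasons
        if not removal:
            reason = "no variable qualified for removal"
            break
        if len(removal) >= len(current):
            keep_n = max(1, math.ceil(len(current) / 10))
            order = np.argsort(-vips)
            keep = {current[j] for j in order[:keep_n]}
            removal = {v: r for v, r in removal.items() if v not in keep}
            it.removed = removal
            current = [v for v in current if v in keep]
            warnings.warn("iterative selection would remove every variable; "
                          f"keeping the top {keep_n} by VIP", stacklevel=2)
            reason = "all variables qualified; kept top VIP fraction"
            if len(current) >= 1:
                A_fin = min(A, len(current), X.shape[0] - 1)
                m = fit_pls(X[current], y, A_fin)
                rep = cross_validate(X[current], y, A_fin, K)
                iterations.append(SelectionIteration(
                    variables=list(current), q2=rep.q2, q2_se=rep.q2_se,
                    r2y=m.r2y, cv_anova_p=cv_anova(rep).p_value))
            break
        it.removed = removal
        current = [v for v in current if v not in removal]
        if len(current) < 2:
            reason = "fewer than 2 variables left"
            break

    q2s = [it.q2 for it in iterations]
    max_q2 = max(q2s)
    if q2_tolerance is None:
        eligible = [i for i, it in enumerate(iterations)
                    if it.q2 + it.q2_se >= max_q2]
    else:
        eligible = [i for i, q in enumerate(q2s) if q >= max_q2 - q2_tolerance]
    best_index = min(eligible,
                     key=lambda i: (len(iterations[i].variables), -i))
    best_vars = iterations[best_index].variables
    final = fit_pls(X[best_vars], y, min(A, len(best_vars), X.shape[0] - 1))
    trace = SelectionTrace(iterations=iterations, best_index=best_index,
                           stopped_because=reason)
    logger.info("iterative selection: %d iteration(s), best Q²=%.3f with %d "
                "variable(s) (%s)", len(iterations),
                iterations[best_index].q2, len(best_vars), reason)
    return trace, final
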