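"""Partial least squares regression and discriminant analysis.

NIPALS decomposition with deflation of both X and Y, z-scored inputs, and the
surrounding model-building protocol:

* the number of latent variables (LVs) is chosen by 3-fold cross-validation
  ("one-third of the dataset" holdouts, every sample predicted once),
  minimizing cumulative held-out error, ties to the smaller model;
* model confidence comes from rebuilding the model on label/response-permuted
  data and comparing the true model's per-held-out-sample CV errors to the
  pooled permuted ones with a one-sided Mann-Whitney U test;
* variable importance in projection (VIP) summarizes each predictor's
  contribution across LVs, normalized so the mean squared VIP is 1; scores
  above 1 are flagged as above-average contributors;
* fitted models can be orthogonally rotated so that maximal class separation
  (or covariance with Y) lies along LV1; rotation never changes predictions.

Discriminant mode encodes classes as one indicator column per class and
decodes predictions by argmax (ties to class order).
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, mannwhitneyu

logger = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


class PLSError(ValueError):
    pass


def zscore_fit(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Column-wise z-scoring (sample SD); returns the standardized table and
    the parameters needed to apply or invert the mapping."""
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise PLSError(f"zero-variance columns cannot be z-scored: {zero}")
    return (table - mean) / sd, {"mean": mean, "sd": sd}


def zscore_apply(table: pd.DataFrame, params: dict) -> pd.DataFrame:
    return (table - params["mean"]) / params["sd"]


def zscore_invert(table: pd.DataFrame, params: dict) -> pd.DataFrame:
    return table * params["sd"] + params["mean"]


def _encode_classes(labels: Sequence) -> tuple[pd.DataFrame, np.ndarray]:
    y = pd.Series(list(labels))
    classes = np.array(sorted(y.unique(), key=str))
    Y = pd.DataFrame({f"class_{c}": (y == c).astype(float).to_numpy() for c in classes})
    return Y, classes


@dataclasses.dataclass
class PLSModel:
    """Fitted PLS decomposition (possibly rotated)."""

    mode: str  # "regression" | "discriminant"
    n_components: int
    x_columns: list[str]
    y_columns: list[str]
    x_params: dict
    y_params: dict
    W: np.ndarray  # predictor weights, p x A (rotated if rotation applied)
    P: np.ndarray  # X loadings, p x A
    Q: np.ndarray  # Y loadings, q x A
    T: np.ndarray  # scores, n x A
    W0: np.ndarray  # unrotated weights (normalized columns), for VIP
    ssy: np.ndarray  # Y sum of squares explained per (unrotated) LV
    ssx: np.ndarray  # X sum of squares explained per (unrotated) LV
    ssy_total: float
    ssx_total: float
    rotation: np.ndarray  # A x A orthogonal; identity if unrotated
    classes: np.ndarray | None = None
    labels: np.ndarray | None = None  # training labels (discriminant)
    y_std: np.ndarray | None = None  # standardized training Y
    cv_error: dict | None = None
    permutation_p: float | None = None
    seed: int | None = None

    @property
    def coef_matrix(self) -> np.ndarray:
        """Regression matrix B with Yhat_std = X_std @ B (rotation-invariant)."""
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return R @ self.Q.T

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Xs = zscore_apply(X[self.x_columns], self.x_params).to_numpy(dtype=float)
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return Xs @ R

    def predict_response(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = zscore_apply(X[self.x_columns], self.x_params).to_numpy(dtype=float)
        Ys = Xs @ self.coef_matrix
        out = pd.DataFrame(Ys, columns=self.y_columns, index=X.index)
        return zscore_invert(out, self.y_params)

    def predict(self, X: pd.DataFrame):
        Y = self.predict_response(X)
        if self.mode == "regression":
            return Y
        # argmax decoding; np.argmax takes the first maximum -> class-order ties
        return self.classes[np.argmax(Y.to_numpy(), axis=1)]

    def explained_y_fraction(self) -> np.ndarray:
        return self.ssy / self.ssy_total

    def explained_x_fraction(self) -> np.ndarray:
        return self.ssx / self.ssx_total


def _nipals(X: np.ndarray, Y: np.ndarray, A: int):
    Xr, Yr = X.copy(), Y.copy()
    n, p = X.shape
    q = Y.shape[1]
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((q, A))
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    ssx = np.zeros(A)
    for a in range(A):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = np.ones(n)
        t_old = np.zeros(n)
        for _ in range(NIPALS_MAX_ITER):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                raise PLSError(f"NIPALS: degenerate weight vector at component {a + 1}")
            w /= nw
            t = Xr @ w
            tt = t @ t
            if tt < 1e-14:
                raise PLSError(f"NIPALS: degenerate scores at component {a + 1}")
            qv = Yr.T @ t / tt
            if np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
            qq = qv @ qv
            u = Yr @ qv / qq if qq > 1e-14 else t
        pv = Xr.T @ t / tt
        Xr -= np.outer(t, pv)
        Yr -= np.outer(t, qv)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
        ssy[a] = tt * (qv @ qv)
        ssx[a] = tt * (pv @ pv)
    return W, P, Q, T, ssy, ssx


def fit_pls(
    X: pd.DataFrame,
    Y,
    n_components: int,
    mode: str = "regression",
    seed: int | None = None,
) -> PLSModel:
    """Fit a PLS model; inputs are z-scored internally (parameters stored)."""
    if mode not in ("regression", "discriminant"):
        raise PLSError(f"unknown mode {mode!r}")
    X = pd.DataFrame(X)
    if X.isna().any().any():
        raise PLSError("NaN in predictors")
    classes = labels = None
    if mode == "discriminant":
        Ydf, classes = _encode_classes(Y)
        labels = np.asarray(list(Y))
        if len(classes) < 2:
            raise PLSError("discriminant mode needs >= 2 classes")
    else:
        Ydf = pd.DataFrame(Y)
        if isinstance(Y, pd.Series):
            Ydf = Y.to_frame()
        if Ydf.isna().any().any():
            raise PLSError("NaN in responses")
    n, p = X.shape
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise PLSError(f"n_components must lie in [1, {max_a}]")
    Xs_df, x_params = zscore_fit(X)
    Ys_df, y_params = zscore_fit(Ydf)
    Xs = Xs_df.to_numpy(dtype=float)
    Ys = Ys_df.to_numpy(dtype=float)
    if n_components > np.linalg.matrix_rank(Xs):
        raise PLSError("n_components exceeds the rank of the predictor matrix")
    W, P, Q, T, ssy, ssx = _nipals(Xs, Ys, n_components)
    return PLSModel(
        mode=mode,
        n_components=n_components,
        x_columns=list(X.columns),
        y_columns=list(Ydf.columns),
        x_params=x_params,
        y_params=y_params,
        W=W, P=P, Q=Q, T=T, W0=W.copy(),
        ssy=ssy, ssx=ssx,
        ssy_total=float((Ys ** 2).sum()),
        ssx_total=float((Xs ** 2).sum()),
        rotation=np.eye(n_components),
        classes=classes,
        labels=labels,
        y_std=Ys,
        seed=seed,
    )


def vip_scores(model: PLSModel) -> pd.Series:
    """VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a).

    Uses the unrotated, column-normalized weights, so the mean squared VIP is
    exactly 1; entries above 1 mark above-average contributors.
    """
    p = len(model.x_columns)
    ssy = model.ssy
    if ssy.sum() <= 0:
        raise PLSError("model explains no Y variance; VIP undefined")
    vip = np.sqrt(p * (model.W0 ** 2) @ ssy / ssy.sum())
    return pd.Series(vip, index=model.x_columns, name="vip")


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator,
                     labels: np.ndarray | None) -> np.ndarray:
    fold = np.empty(n, dtype=int)
    if labels is None:
        fold[rng.permutation(n)] = np.arange(n) % n_folds
        return fold
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _cv_per_sample_errors(
    X: pd.DataFrame,
    Y,
    n_components: int,
    mode: str,
    fold: np.ndarray,
) -> np.ndarray:
    """Held-out error per sample: squared error (regression, summed over Y
    columns) or 0/1 misclassification (discriminant)."""
    n = len(X)
    errors = np.empty(n)
    y_arr = np.asarray(list(Y)) if mode == "discriminant" else np.asarray(pd.DataFrame(Y))
    for f in np.unique(fold):
        train, test = fold != f, fold == f
        # columns constant within this training fold carry no usable signal
        sd = X.iloc[train].std(axis=0, ddof=1)
        Xf = X.loc[:, sd > 0]
        a_eff = min(n_components, int(train.sum()) - 1, Xf.shape[1])
        model = fit_pls(Xf.iloc[train], (np.asarray(list(Y))[train] if mode == "discriminant"
                                         else pd.DataFrame(Y).iloc[train]),
                        a_eff, mode=mode)
        if mode == "discriminant":
            pred = model.predict(X.iloc[test])
            errors[test] = (pred != y_arr[test]).astype(float)
        else:
            pred = model.predict_response(X.iloc[test]).to_numpy()
            errors[test] = ((pred - y_arr[test]) ** 2).sum(axis=1)
    return errors


def select_n_lv(
    X: pd.DataFrame,
    Y,
    a_grid: Sequence[int],
    n_folds: int = 3,
    seed: int = 0,
    mode: str = "regression",
) -> tuple[int, dict[int, float]]:
    """Choose the LV count minimizing cumulative 3-fold held-out error.

    Error is root-mean-squared prediction error (regression) or the
    misclassification fraction (discriminant), cumulated over all held-out
    predictions; ties go to the smaller model. Folds are stratified by class
    in discriminant mode; a training fold missing a class is re-drawn.
    """
    X = pd.DataFrame(X)
    n = len(X)
    if n < 6:
        raise PLSError("need >= 6 samples for cross-validated LV selection")
    labels = np.asarray(list(Y)) if mode == "discriminant" else None
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        fold = _fold_assignment(n, n_folds, rng, labels)
        if labels is None:
            break
        if all(len(np.unique(labels[fold != f])) == len(np.unique(labels))
               for f in np.unique(fold)):
            break
        logger.info("select_n_lv: training fold lost a class, re-drawing")
    curve: dict[int, float] = {}
    for a in a_grid:
        errs = _cv_per_sample_errors(X, Y, a, mode, fold)
        curve[a] = float(np.mean(errs)) if mode == "discriminant" else float(np.sqrt(np.mean(errs)))
    best = min(curve, key=lambda a: (curve[a], a))
    return int(best), curve


def _axis1_criterion(T1: np.ndarray, model_labels, y_std, criterion: str) -> float:
    if criterion == "class_separation":
        labels = model_labels
        grand = T1.mean()
        between = sum((T1[labels == c].mean() - grand) ** 2 * (labels == c).sum()
                      for c in np.unique(labels))
        total = ((T1 - grand) ** 2).sum()
        return between / total if total > 0 else 0.0
    if criterion == "y_covariance":
        return float(np.abs((T1 - T1.mean()) @ (y_std - y_std.mean(axis=0))).sum())
    raise PLSError(f"unknown rotation criterion {criterion!r}")


def _givens(A: int, i: int, j: int, theta: float) -> np.ndarray:
    G = np.eye(A)
    c, s = np.cos(theta), np.sin(theta)
    G[i, i] = G[j, j] = c
    G[i, j] = -s
    G[j, i] = s
    return G


def orthogonal_rotate(model: PLSModel, criterion: str = "class_separation") -> PLSModel:
    """Rotate the LV basis so the criterion is maximal along axis 1.

    Searches orthogonal A x A matrices as products of Givens rotations in the
    (1, j) planes (a single angle search for A = 2). Scores, loadings and
    weights rotate together, so fitted predictions are unchanged.
    """
    A = model.n_components
    if A < 2:
        logger.info("orthogonal_rotate: single component, identity rotation")
        return dataclasses.replace(model, rotation=np.eye(A))
    if criterion == "class_separation" and model.labels is None:
        raise PLSError("class_separation rotation needs a discriminant model")
    T = model.T
    R_total = np.eye(A)

    def crit(Tcur):
        return _axis1_criterion(Tcur[:, 0], model.labels, model.y_std, criterion)

    Tcur = T.copy()
    for _sweep in range(10):
        improved = False
        for j in range(1, A):
            def neg(theta, j=j):
                G = _givens(A, 0, j, theta)
                return -crit(Tcur @ G)
            grid = np.linspace(0.0, np.pi, 181, endpoint=False)
            vals = [neg(t) for t in grid]
            t0 = grid[int(np.argmin(vals))]
            res = optimize.minimize_scalar(
                neg, bounds=(t0 - np.pi / 180, t0 + np.pi / 180), method="bounded",
                options={"xatol": 1e-10},
            )
            theta = res.x if res.fun < neg(t0) else t0
            if -neg(theta) > crit(Tcur) + 1e-12:
                G = _givens(A, 0, j, theta)
                Tcur = Tcur @ G
                R_total = R_total @ G
                improved = True
        if not improved:
            break
    return dataclasses.replace(
        model,
        W=model.W @ R_total,
        P=model.P @ R_total,
        Q=model.Q @ R_total,
        T=model.T @ R_total,
        rotation=model.rotation @ R_total,
    )


def permutation_significance(
    X: pd.DataFrame,
    Y,
    a_grid: Sequence[int],
    n_perm: int = 100,
    seed: int = 0,
    mode: str = "regression",
    n_folds: int = 3,
    reselect_a: bool = True,
) -> tuple[float, dict]:
    """Model confidence by Y-permutation.

    The true model's per-held-out-sample CV errors (one per sample, at the
    CV-selected LV count) are compared against the pooled per-sample CV errors
    of ``n_perm`` Y-permuted rebuilds by a one-sided Mann-Whitney U test
    (true errors smaller). By default the LV count is re-selected inside each
    permutation; ``reselect_a=False`` freezes the true model's choice.

    Returns ``(p_value, detail)`` with the selected A, the CV curve and the
    per-sample error arrays in ``detail``.
    """
    if n_perm < 20:
        raise PLSError("n_perm must be >= 20 for a usable rank test")
    X = pd.DataFrame(X)
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(Y)) if mode == "discriminant" else None

    a_star, curve = select_n_lv(X, Y, a_grid, n_folds=n_folds, seed=seed, mode=mode)
    fold = _fold_assignment(len(X), n_folds, np.random.default_rng(seed), labels)
    true_errors = _cv_per_sample_errors(X, Y, a_star, mode, fold)

    perm_errors = []
    y_list = np.asarray(list(Y)) if mode == "discriminant" else pd.DataFrame(Y).to_numpy()
    for b in range(n_perm):
        perm_idx = rng.permutation(len(X))
        Yp = y_list[perm_idx]
        Yp_obj = Yp if mode == "discriminant" else pd.DataFrame(Yp)
        if reselect_a:
            a_b, _ = select_n_lv(X, Yp_obj, a_grid, n_folds=n_folds,
                                 seed=seed + b + 1, mode=mode)
        else:
            a_b = a_star
        fold_b = _fold_assignment(len(X), n_folds,
                                  np.random.default_rng(seed + b + 1),
                                  Yp if mode == "discriminant" else None)
        perm_errors.append(_cv_per_sample_errors(X, Yp_obj, a_b, mode, fold_b))
    pooled = np.concatenate(perm_errors)
    stat = mannwhitneyu(true_errors, pooled, alternative="less")
    return float(stat.pvalue), {
        "a_star": a_star,
        "cv_curve": curve,
        "true_errors": true_errors,
        "perm_errors": pooled,
    }


@dataclasses.dataclass
class EllipseParams:
    center: np.ndarray
    radii: np.ndarray  # semi-axes
    angle: float  # radians, orientation of the first axis


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> EllipseParams:
    """Gaussian confidence ellipse of a 2-column score matrix.

    Semi-axes scale the score covariance eigenvalues by the chi-square(2)
    quantile at ``level``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise PLSError("confidence_ellipse needs exactly 2 score columns")
    if len(scores) < 3:
        raise PLSError("need >= 3 samples")
    if not 0.0 <= level < 1.0:
        raise PLSError("level must lie in [0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise PLSError("singular score covariance")
    evals, evecs = np.linalg.eigh(cov)
    quant = chi2.ppf(level, df=2) if level > 0 else 0.0
    radii = np.sqrt(evals[::-1] * quant)
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return EllipseParams(center=center, radii=radii, angle=angle)
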