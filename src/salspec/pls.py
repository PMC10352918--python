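"""Univariate partial least squares regression (PLS1) core.

Everything downstream — wavelength selection, the calibration models, and the
cross-validated latent-variable scans inside CARS and random frog — runs on
this NIPALS implementation. For a single response NIPALS is non-iterative
(one weight/score/deflation pass per component), and keeping the component
sequence explicit lets one fitted model yield predictions for *every*
component count 1..A at once, which makes RMSECV-over-LV scans cheap.

X columns are centred (and optionally scaled by a user-supplied vector,
e.g. unit scale for reflectance bands and autoscaling for growth covariates);
y is centred. A fitted model therefore maps the training-mean input to the
training-mean response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "fit_plsr", "predict_components", "rmsecv_scan", "rmsecv", "best_lv"]

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    Attributes
    ----------
    n_lv : number of latent variables actually fitted (may be truncated below
        the request if X runs out of rank; see ``fit_plsr``).
    weights, loadings : (p, A) NIPALS weight and X-loading matrices.
    y_loadings : (A,) per-component y loadings.
    coef_, intercept_ : regression coefficients on the original (unscaled)
        input scale, so ``predict(X) = X @ coef_ + intercept_``.
    """

    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    coef_: np.ndarray
    intercept_: float
    feature_names: list[str] | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def _nipals(Xc: np.ndarray, yc: np.ndarray, a_max: int):
    """Run PLS1 NIPALS on centred data; returns (W, P, q, T) truncated at rank."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    T = np.zeros((n, a_max))
    used = 0
    ynorm0 = float(np.linalg.norm(yc)) or 1.0
    for a in range(a_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * ynorm0:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _EPS * n:
            break
        pl = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pl)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, qa, t
        used = a + 1
    return W[:, :used], P[:, :used], q[:used], T[:, :used]


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    x_scale: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    allow_truncation: bool = True,
) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    Parameters
    ----------
    x_scale : optional per-column divisor applied after centring (defaults to
        no scaling). Coefficients are reported back on the original scale.
    allow_truncation : if the data rank is exhausted before ``n_lv``
        components, keep the components found (True) or raise (False).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    if n_lv <= 0:
        raise ValueError("n_lv must be >= 1")
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} exceeds min(n-1, p)={min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    if x_scale is None:
        x_scale = np.ones(p)
    else:
        x_scale = np.asarray(x_scale, dtype=float)
        if np.any(x_scale <= 0):
            raise ValueError("x_scale entries must be positive")
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean
    W, P, q, _ = _nipals(Xc, yc, n_lv)
    if W.shape[1] < n_lv and not allow_truncation:
        raise ValueError(f"rank exhausted at {W.shape[1]} < requested {n_lv} components")
    used = W.shape[1]
    if used == 0:  # constant y: coefficient zero, predict the mean
        coef = np.zeros(p)
    else:
        # beta = W (P'W)^{-1} q on the centred/scaled space
        R = np.linalg.solve((P.T @ W).T, W.T).T  # W @ inv(P'W)
        coef = (R @ q) / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_lv=used,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        coef_=coef,
        intercept_=intercept,
        feature_names=feature_names,
    )


def predict_components(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predictions for every component count 1..model.n_lv.

    Returns an (n, A) array whose column a-1 is the prediction using the first
    a latent variables. Used to evaluate a whole LV scan from one fit.
    """
    X = np.asarray(X, dtype=float)
    Xc = (X - model.x_mean) / model.x_scale
    n = Xc.shape[0]
    A = model.weights.shape[1]
    if A == 0:
        return np.full((n, 1), model.y_mean)
    out = np.empty((n, A))
    acc = np.zeros(n)
    Xd = Xc.copy()
    for a in range(A):
        t = Xd @ model.weights[:, a]
        acc += model.y_loadings[a] * t
        Xd -= np.outer(t, model.loadings[:, a])
        out[:, a] = acc + model.y_mean
    return out


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), folds)]


def rmsecv_scan(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: int = 5,
    seed: int = 0,
    x_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-validated RMSE for every component count 1..max_lv.

    Fold assignment is a seeded permutation split into ``folds`` contiguous
    blocks, so results are reproducible given the seed. If a fold's training
    data supports fewer than ``max_lv`` components, that fold contributes its
    deepest available prediction to the larger counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds < 2 or folds > n:
        raise ValueError("need 2 <= folds <= n")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    cap = min(max_lv, n - int(np.ceil(n / folds)) - 1, p)
    if cap < 1:
        raise ValueError("no feasible number of latent variables for this CV layout")
    sse = np.zeros(cap)
    for test in _fold_indices(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test)
        model = fit_plsr(X[train], y[train], cap, x_scale=x_scale)
        pred = predict_components(model, X[test])  # (n_test, A_fold)
        # pad to cap with the deepest available column
        if pred.shape[1] < cap:
            pad = np.repeat(pred[:, -1:], cap - pred.shape[1], axis=1)
            pred = np.hstack([pred, pad])
        sse += ((pred - y[test, None]) ** 2).sum(axis=0)
    return np.sqrt(sse / n)


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    folds: int = 5,
    seed: int = 0,
    x_scale: np.ndarray | None = None,
) -> float:
    """Cross-validated RMSE (dS/m for salinity targets) at a fixed LV count."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    feasible = min(n - int(np.ceil(n / folds)) - 1, X.shape[1])
    if n_lv < 1 or n_lv > feasible:
        raise ValueError(f"n_lv={n_lv} infeasible (max {feasible})")
    return float(rmsecv_scan(X, y, n_lv, folds=folds, seed=seed, x_scale=x_scale)[n_lv - 1])


def best_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    folds: int = 5,
    seed: int = 0,
    x_scale: np.ndarray | None = None,
) -> tuple[int, float, np.ndarray]:
    """Pick the LV count minimising RMSECV; ties go to the smaller count.

    Returns ``(n_lv, rmsecv_at_n_lv, full_scan)``.
    """
    scan = rmsecv_scan(X, y, max_lv, folds=folds, seed=seed, x_scale=x_scale)
    idx = int(np.argmin(scan))  # argmin returns the first (= smallest LV) on ties
    return idx + 1, float(scan[idx]), scan
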