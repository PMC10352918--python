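"""Wavelength selection for PLS calibration.

Three selectors, all scored by cross-validated RMSE (RMSECV) of a PLS1 model
on the candidate band subset:

* **VIP** — variable importance in projection. For an A-component PLS fit,
  VIP_j = sqrt(K * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a) where SSY_a is
  the response variance explained by component a and w_a the component
  weights. The scores satisfy sum_j VIP_j^2 = K, so the mean squared score is
  exactly 1 and bands scoring above 1 are the informative ones.

* **CARS** — competitive adaptive reweighted sampling. N Monte-Carlo runs; at
  run i a PLS model fitted on a random sample fraction ranks the surviving
  bands by |regression coefficient|, an exponentially decaying ratio
  r_i = a*exp(-k*i) (calibrated so run 1 keeps all p bands and run N keeps 2)
  caps how many survive, and adaptive reweighted sampling (weighted draws
  with replacement) thins them further. The run subset with the smallest
  RMSECV wins.

* **Random frog** — an MCMC-flavoured subset walk: from the current subset a
  normal proposal perturbs the subset size; shrinking keeps the bands with
  the largest |coefficient|, growing adds random bands; a worse subset is
  accepted with probability eta*(RMSECV_old/RMSECV_new). A band's selection
  probability is its inclusion frequency over the post-burn-in chain, pooled
  over restarts; the returned subset is the best (lowest RMSECV) visited.

Ties on minimal RMSECV break to the smaller subset, then the earlier run —
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .pls import best_lv, fit_plsr, _nipals

__all__ = [
    "SelectionResult",
    "VIPParams",
    "CARSParams",
    "RFAParams",
    "vip_scores",
    "cars_select",
    "random_frog_select",
    "cars_retention_schedule",
]


@dataclass
class SelectionResult:
    """Outcome of one selector run.

    ``scores`` is method-specific: VIP scores, CARS per-run retention
    fraction, or random-frog selection probabilities (all per band, aligned
    with ``wavelengths``). ``support`` is the boolean membership mask of the
    selected subset.
    """

    method: str
    wavelengths: np.ndarray
    scores: np.ndarray
    support: np.ndarray
    rmsecv_trace: np.ndarray
    best_rmsecv: float
    n_lv: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.support.any():
            raise ValueError("selection must retain at least one band")

    @property
    def selected_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.support]

    @property
    def n_selected(self) -> int:
        return int(self.support.sum())


@dataclass
class VIPParams:
    n_lv: int | None = None  # None: choose by RMSECV scan
    threshold: float = 1.0
    max_lv: int = 10
    cv_folds: int = 5


@dataclass
class CARSParams:
    n_runs: int = 50
    mc_ratio: float = 0.8
    cv_folds: int = 5
    max_lv: int = 10

    def __post_init__(self):
        if not 0 < self.mc_ratio < 1:
            raise ValueError("mc_ratio must be in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("need at least 2 sampling runs")


@dataclass
class RFAParams:
    n_chain_iters: int = 1000
    burn_in: int = 100
    n_restarts: int = 100
    q_init: int | None = None  # None: round(0.05 * p), at least 2
    theta: float = 0.3
    eta: float = 0.1
    omega: float = 3.0  # candidate-pool multiplier for the growth move
    max_lv: int = 10
    cv_folds: int = 5

    def __post_init__(self):
        if self.n_chain_iters <= self.burn_in:
            raise ValueError("chain must be longer than the burn-in")


def _as_wavelengths(wavelengths, p: int) -> np.ndarray:
    if wavelengths is None:
        return np.arange(p, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if wl.shape[0] != p:
        raise ValueError("wavelengths length must match the band axis")
    return wl


def _eval_subset(X, y, idx, max_lv, folds, seed):
    """(rmsecv, n_lv) for a band subset, LV chosen by the scan."""
    Xs = X[:, idx]
    cap = min(max_lv, Xs.shape[1], X.shape[0] - int(np.ceil(X.shape[0] / folds)) - 1)
    lv, rm, _ = best_lv(Xs, y, max_lv=cap, folds=folds, seed=seed)
    return rm, lv


def vip_scores(X, y, params: VIPParams | None = None, wavelengths=None, seed: int = 0) -> SelectionResult:
    """VIP scores and the >threshold subset.

    If no band clears the threshold (possible only when all scores are ~1),
    the single highest-scoring band is retained so the result is usable.
    """
    params = params or VIPParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    wl = _as_wavelengths(wavelengths, p)
    if params.n_lv is None:
        a, _, _ = best_lv(X, y, max_lv=min(params.max_lv, n - 1, p),
                          folds=params.cv_folds, seed=seed)
    else:
        a = params.n_lv
    if a < 1 or a > min(n - 1, p):
        raise ValueError(f"n_lv={a} infeasible")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    W, P, q, T = _nipals(Xc, yc, a)
    if W.shape[1] < a:
        raise ValueError(f"requested {a} components but rank supports only {W.shape[1]}")
    ssy = q**2 * (T**2).sum(axis=0)  # response variance captured per component
    total = ssy.sum()
    if total <= 0:
        raise ValueError("PLS explained no response variance; VIP undefined")
    vip = np.sqrt(p * (W**2 @ ssy) / total)
    support = vip > params.threshold
    if not support.any():
        support[int(np.argmax(vip))] = True
    rm, lv = _eval_subset(X, y, np.flatnonzero(support), params.max_lv, params.cv_folds, seed)
    return SelectionResult(
        method="VIP",
        wavelengths=wl,
        scores=vip,
        support=support,
        rmsecv_trace=np.array([rm]),
        best_rmsecv=rm,
        n_lv=lv,
        seed=seed,
        params=asdict(params) | {"n_lv_used": int(a)},
    )


def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Enforced retention ratios r_i = a*exp(-k*i), i = 1..N.

    a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1), so r_1 = 1 (all p bands) and
    r_N = 2/p (two bands).
    """
    if p < 2:
        raise ValueError("need at least 2 bands")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cars_select(X, y, params: CARSParams | None = None, wavelengths=None, seed: int = 0) -> SelectionResult:
    """Competitive adaptive reweighted sampling."""
    params = params or CARSParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 bands")
    wl = _as_wavelengths(wavelengths, p)
    rng = np.random.default_rng(seed)
    ratios = cars_retention_schedule(p, params.n_runs)
    n_mc = max(2, int(round(params.mc_ratio * n)))

    retained = np.arange(p)
    runs: list[dict] = []
    retention_counts = np.zeros(p)
    # weight-model LV follows the CV-chosen LV of the current subset (starts
    # from the full spectrum); a fixed deep LV would concentrate coefficients
    # on noise bands and collapse the subset prematurely
    _, weight_lv = _eval_subset(X, y, retained, params.max_lv, params.cv_folds, seed)
    for i, ratio in enumerate(ratios):
        mc = rng.choice(n, size=n_mc, replace=False)
        a = min(weight_lv, n_mc - 1, retained.size)
        model = fit_plsr(X[np.ix_(mc, retained)], y[mc], a)
        w = np.abs(model.coef_)
        if not np.any(w > 0):
            warnings.warn("all-zero PLS coefficients; falling back to uniform weights")
            w = np.ones_like(w)
        keep = int(round(ratio * p))
        keep = max(2, min(keep, retained.size))
        # exponential-decay cap: top `keep` bands by weight
        order = np.argsort(w)[::-1][:keep]
        forced = retained[order]
        wf = w[order]
        # adaptive reweighted sampling among the survivors: p draws with
        # replacement, so the unique count tracks the enforced schedule
        # instead of halving each run
        draws = rng.choice(forced, size=p, replace=True, p=wf / wf.sum())
        new = np.unique(draws)
        if new.size < 2:
            new = np.sort(forced[:2])
        retained = np.sort(new)
        rm, lv = _eval_subset(X, y, retained, params.max_lv, params.cv_folds, seed)
        weight_lv = lv
        retention_counts[retained] += 1
        runs.append(
            {"run": i + 1, "subset": retained.copy(), "rmsecv": rm, "n_lv": lv,
             "enforced_keep": keep}
        )

    trace = np.array([r["rmsecv"] for r in runs])
    best = min(runs, key=lambda r: (r["rmsecv"], r["subset"].size, r["run"]))
    support = np.zeros(p, dtype=bool)
    support[best["subset"]] = True
    return SelectionResult(
        method="CARS",
        wavelengths=wl,
        scores=retention_counts / params.n_runs,
        support=support,
        rmsecv_trace=trace,
        best_rmsecv=float(best["rmsecv"]),
        n_lv=int(best["n_lv"]),
        seed=seed,
        params=asdict(params)
        | {
            "best_run": int(best["run"]),
            "enforced_keep_per_run": [r["enforced_keep"] for r in runs],
            "retained_per_run": [int(r["subset"].size) for r in runs],
        },
    )


def random_frog_select(X, y, params: RFAParams | None = None, wavelengths=None, seed: int = 0) -> SelectionResult:
    """Random frog subset search; probabilities are chain inclusion rates."""
    params = params or RFAParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("random frog needs at least 2 bands")
    wl = _as_wavelengths(wavelengths, p)
    q0 = params.q_init if params.q_init is not None else max(2, int(round(0.05 * p)))
    q0 = min(max(2, q0), p)
    # cap the chain's evaluation depth at the latent depth the full spectrum
    # supports (plus one): an unconstrained deep-LV scan would let the subset
    # walk mine cross-validation structure that does not generalise
    _, lv0 = _eval_subset(X, y, np.arange(p), params.max_lv, params.cv_folds, seed)
    max_lv_eff = min(params.max_lv, lv0 + 1)

    counts = np.zeros(p)
    total = 0
    best_sub = None
    best_rm = np.inf
    best_lv_ = 1
    best_restart = -1
    per_restart_rm = np.empty(params.n_restarts)
    ss = np.random.SeedSequence([seed, 0x52464121])
    for r, child in enumerate(ss.spawn(params.n_restarts)):
        rng = np.random.default_rng(child)
        eval_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        V = np.sort(rng.choice(p, size=q0, replace=False))
        rm_V, lv_V = _eval_subset(X, y, V, max_lv_eff, params.cv_folds, eval_seed)
        chain_counts = np.zeros(p)
        chain_total = 0
        for it in range(params.n_chain_iters):
            qs = V.size
            q_star = int(round(rng.normal(qs, params.theta * qs)))
            q_star = min(max(2, q_star), p)
            if q_star < qs:
                a = min(max_lv_eff, n - 1, qs)
                coefs = np.abs(fit_plsr(X[:, V], y, a).coef_)
                V_star = np.sort(V[np.argsort(coefs)[::-1][:q_star]])
            elif q_star > qs:
                # directed growth: draw an omega-fold candidate pool, keep the
                # candidates with the largest |coefficient| in a trial fit
                pool = np.setdiff1d(np.arange(p), V, assume_unique=False)
                grow = min(q_star - qs, pool.size)
                cand = rng.choice(pool, size=min(int(params.omega * grow), pool.size),
                                  replace=False)
                trial = np.concatenate([V, cand])
                a = min(max_lv_eff, n - 1, trial.size)
                coefs = np.abs(fit_plsr(X[:, trial], y, a).coef_[qs:])
                add = cand[np.argsort(coefs)[::-1][:grow]]
                V_star = np.sort(np.concatenate([V, add]))
            else:
                pool = np.setdiff1d(np.arange(p), V)
                V_star = V.copy()
                if pool.size:
                    V_star[rng.integers(qs)] = rng.choice(pool)
                V_star = np.sort(V_star)
            rm_star, lv_star = _eval_subset(
                X, y, V_star, max_lv_eff, params.cv_folds, eval_seed
            )
            accept = rm_star <= rm_V or rng.random() < params.eta * (rm_V / rm_star)
            if accept:
                V, rm_V, lv_V = V_star, rm_star, lv_star
            if it >= params.burn_in:
                counts[V] += 1
                chain_counts[V] += 1
                total += 1
                chain_total += 1
        # restart candidate = bands the chain included most of the time;
        # picking the raw chain-best subset instead would reward whichever
        # of the thousands of CV evaluations got lucky
        probs_r = chain_counts / max(chain_total, 1)
        cand = np.flatnonzero(probs_r > 0.5)
        if cand.size < 2:
            cand = np.argsort(probs_r)[::-1][:max(2, min(q0, p))]
            cand = np.sort(cand)
        rm_c, lv_c = _eval_subset(X, y, cand, max_lv_eff, params.cv_folds, eval_seed)
        per_restart_rm[r] = rm_c
        if (rm_c, cand.size) < (best_rm, 0 if best_sub is None else best_sub.size):
            best_rm, best_sub, best_lv_, best_restart = rm_c, cand, lv_c, r

    support = np.zeros(p, dtype=bool)
    support[best_sub] = True
    return SelectionResult(
        method="RFA",
        wavelengths=wl,
        scores=counts / max(total, 1),
        support=support,
        rmsecv_trace=per_restart_rm,
        best_rmsecv=float(best_rm),
        n_lv=int(best_lv_),
        seed=seed,
        params=asdict(params) | {"q_init_used": int(q0), "best_restart": int(best_restart)},
    )
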