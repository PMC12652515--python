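"""Wavelength-variable selection: CARS and SPA.

CARS (competitive adaptive reweighted sampling) couples Monte-Carlo row
subsampling with PLS coefficient weighting: an exponentially decreasing
forced-retention schedule shrinks the variable set from p to 2 over the run,
and adaptive reweighted sampling keeps variables in proportion to their
coefficient magnitude. Because single runs are stochastic, the
frequency-based variant repeats the run (default 50 times), counts how often
each wavelength lands in a run's best subset, and sweeps occupied
repeat-count thresholds, scoring each thresholded subset by 10-fold RMSECV
(regression, PLSR) or ACCCV (classification, PLS-DA).

SPA (successive projections algorithm) builds minimally collinear candidate
chains by repeated orthogonal projection, scores candidate sets by
cross-validated MLR PRESS, and backward-eliminates variables whose removal
does not worsen PRESS beyond a relative tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .chemometric_models import _one_hot, plsr_cv_rmse, plsda_cv_metrics

OBJECTIVES = ("rmsecv_plsr", "acccv_plsda")


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------


@dataclass
class CarsRunResult:
    retained_sets: list  # per-iteration variable index arrays
    objectives: np.ndarray  # per-iteration CV objective on the retained set
    best_iteration: int
    best_subset: np.ndarray
    best_objective: float
    objective: str


def cars_schedule(p: int, n_iterations: int) -> np.ndarray:
    """Forced retention counts per iteration: r_i = a*exp(-k*i) with a, k
    fixed so iteration 1 retains all p variables and iteration N retains 2."""
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    N = n_iterations
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    r = a * np.exp(-k * i)
    return np.maximum(2, np.round(r * p).astype(int))


def _pls_weights(X, Y, max_components: int) -> np.ndarray:
    ncomp = max(1, min(max_components, X.shape[0] - 1, X.shape[1]))
    pls = PLSRegression(n_components=ncomp, scale=False).fit(X, Y)
    coef = np.atleast_2d(pls.coef_)
    return np.abs(coef).sum(axis=0) if coef.shape[1] == X.shape[1] else np.abs(coef).sum(axis=1)


def _cv_objective(X, y, objective, folds, seed, max_lv):
    if objective == "rmsecv_plsr":
        return plsr_cv_rmse(X, y, max_lv=max_lv, folds=folds, seed=seed)
    return plsda_cv_metrics(X, y, max_lv=max_lv, folds=folds, seed=seed)["acccv"]


def cars_run(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    n_iterations: int = 50,
    folds: int = 5,
    seed: int = 0,
    objective: str = "rmsecv_plsr",
    mc_fraction: float = 0.8,
    max_components: int = 10,
) -> CarsRunResult:
    """One CARS run. Returns per-iteration retained sets and CV objectives
    with the best iteration flagged (minimum RMSECV / maximum ACCCV)."""
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    X = np.asarray(X_cal, float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if folds > n:
        raise ValueError("fold count exceeds sample count")
    y = np.asarray(y_cal)
    is_reg = objective == "rmsecv_plsr"
    Y = y.astype(float)[:, None] if is_reg else _one_hot(y, np.unique(y))
    rng = np.random.default_rng(seed)
    schedule = cars_schedule(p, n_iterations)
    retained = np.arange(p)
    retained_sets, objectives = [], []
    m = max(2, int(round(mc_fraction * n)))
    for it in range(n_iterations):
        rows = rng.choice(n, size=m, replace=False)
        w = _pls_weights(X[np.ix_(rows, retained)], Y[rows], max_components)
        # enforced retention: top-k by weight (stable order, so weight ties
        # keep the lower wavelength index)
        k = min(int(schedule[it]), len(retained))
        order = np.argsort(-w, kind="stable")[:k]
        forced = retained[np.sort(order)]
        fw = w[np.sort(order)]
        # adaptive reweighted sampling: k draws with replacement, weight-
        # proportional; the retained set is the unique draw
        prob = fw / fw.sum() if fw.sum() > 0 else np.full(len(fw), 1.0 / len(fw))
        drawn = rng.choice(len(forced), size=k, replace=True, p=prob)
        retained = forced[np.unique(drawn)]
        if len(retained) < 2:  # keep the subset PLS-viable
            retained = forced[:2]
        retained_sets.append(retained.copy())
        objectives.append(
            _cv_objective(X[:, retained], y, objective, folds, seed, max_components)
        )
    objectives = np.asarray(objectives)
    best_it = int(np.argmin(objectives) if is_reg else np.argmax(objectives))
    return CarsRunResult(
        retained_sets=retained_sets,
        objectives=objectives,
        best_iteration=best_it,
        best_subset=retained_sets[best_it],
        best_objective=float(objectives[best_it]),
        objective=objective,
    )


@dataclass
class FrequencySelection:
    counts: np.ndarray  # selection count per wavelength over the repeats
    sweep: pd.DataFrame  # threshold -> subset size -> objective
    chosen_threshold: int
    chosen_subset: np.ndarray
    chosen_objective: float
    objective: str


def cars_frequency_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    repeats: int = 50,
    n_iterations: int = 50,
    folds: int = 10,
    run_folds: int = 5,
    seed: int = 0,
    objective: str = "rmsecv_plsr",
    max_components: int = 10,
    max_lv: int = 15,
) -> FrequencySelection:
    """Repeat CARS with distinct seeds, count best-subset membership per
    wavelength, and pick the repeat-count threshold whose subset optimizes
    the 10-fold CV objective (ties toward the smaller subset)."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(X_cal, float)
    p = X.shape[1]
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=repeats)
    counts = np.zeros(p, dtype=int)
    for s in child_seeds:
        run = cars_run(
            X,
            y_cal,
            n_iterations=n_iterations,
            folds=run_folds,
            seed=int(s),
            objective=objective,
            max_components=max_components,
        )
        counts[run.best_subset] += 1
    if counts.sum() == 0:
        raise ValueError("no wavelength was ever selected")
    is_reg = objective == "rmsecv_plsr"
    rows = []
    for t in np.unique(counts[counts > 0]):
        subset = np.flatnonzero(counts >= t)
        if len(subset) < 2:
            continue
        obj = _cv_objective(X[:, subset], y_cal, objective, folds, seed, max_lv)
        rows.append(dict(threshold=int(t), size=len(subset), objective=obj))
    sweep = pd.DataFrame(rows)
    if is_reg:
        best_row = sweep.sort_values(["objective", "size"], ascending=[True, True]).iloc[0]
    else:
        best_row = sweep.sort_values(["objective", "size"], ascending=[False, True]).iloc[0]
    t = int(best_row["threshold"])
    return FrequencySelection(
        counts=counts,
        sweep=sweep,
        chosen_threshold=t,
        chosen_subset=np.flatnonzero(counts >= t),
        chosen_objective=float(best_row["objective"]),
        objective=objective,
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------


@dataclass
class SpaResult:
    chains: dict  # start column -> projection chain (list of indices)
    press_table: pd.DataFrame  # candidate (start, m) -> PRESS
    selected: np.ndarray
    press: float


def _mlr_press(X: np.ndarray, y: np.ndarray, cols: np.ndarray, splits) -> float:
    """Cross-validated PRESS of an intercept MLR on the given columns; a
    rank-deficient design falls back to a small ridge with a warning."""
    Xc = X[:, cols]
    sse = 0.0
    for tr, te in splits:
        A = np.hstack([Xc[tr], np.ones((len(tr), 1))])
        beta, _, rank, _ = np.linalg.lstsq(A, y[tr], rcond=None)
        if rank < A.shape[1]:
            warnings.warn("collinear MLR design; using ridge fallback", RuntimeWarning)
            AtA = A.T @ A + 1e-8 * np.eye(A.shape[1])
            beta = np.linalg.solve(AtA, A.T @ y[tr])
        r = y[te] - np.hstack([Xc[te], np.ones((len(te), 1))]) @ beta
        sse += float(r @ r)
    return sse


def _projection_chain(Xs: np.ndarray, start: int, m_max: int) -> list[int]:
    R = Xs.copy()
    chain = [start]
    c = R[:, start].copy()
    while len(chain) < m_max:
        nc = float(c @ c)
        if nc <= 1e-12:
            break
        R = R - np.outer(c, (c @ R) / nc)
        norms = np.sum(R**2, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))  # argmax ties -> smallest index
        if norms[nxt] <= 1e-12:
            break
        chain.append(nxt)
        c = R[:, nxt].copy()
    return chain


def spa_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    m_min: int = 1,
    m_max: int | None = None,
    folds: int = 5,
    seed: int = 0,
    backward_tol: float = 1e-3,
) -> SpaResult:
    """Successive projections selection with CV-MLR PRESS scoring and
    relevance-ordered backward elimination.

    Relevance of a selected variable is |MLR coefficient| times the column's
    standard deviation; elimination removes the least relevant variable while
    PRESS does not worsen by more than ``backward_tol`` (relative).
    """
    X = np.asarray(X_cal, float)
    y = np.asarray(y_cal, float).ravel()
    n, p = X.shape
    m_max = m_max if m_max is not None else min(n - 1, p, 30)
    if not (1 <= m_min <= m_max <= min(n - 1, p)):
        raise ValueError("require 1 <= m_min <= m_max <= min(N-1, p)")
    col_sd = X.std(axis=0)
    sd_safe = np.where(col_sd == 0, 1.0, col_sd)
    Xs = (X - X.mean(axis=0)) / sd_safe
    splits = list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.arange(n)))
    chains = {}
    rows = []
    best = None  # (press, m, start, cols)
    for start in range(p):
        chain = _projection_chain(Xs, start, m_max)
        chains[start] = chain
        for m in range(m_min, min(m_max, len(chain)) + 1):
            cols = np.array(chain[:m])
            press = _mlr_press(X, y, cols, splits)
            rows.append(dict(start=start, m=m, press=press))
            key = (press, m, start)
            if best is None or key < best[0]:
                best = (key, cols)
    press_best, cols = best[0][0], best[1]
    # backward elimination in relevance order
    while len(cols) > 1:
        A = np.hstack([X[:, cols], np.ones((n, 1))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        relevance = np.abs(beta[:-1]) * col_sd[cols]
        removed = False
        for j in np.argsort(relevance, kind="stable"):
            trial = np.delete(cols, j)
            press_trial = _mlr_press(X, y, trial, splits)
            if press_trial <= press_best * (1.0 + backward_tol):
                cols, press_best = trial, min(press_best, press_trial)
                removed = True
                break
        if not removed:
            break
    return SpaResult(
        chains=chains,
        press_table=pd.DataFrame(rows),
        selected=np.sort(cols),
        press=press_best,
    )
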