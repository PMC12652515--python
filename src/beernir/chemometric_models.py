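"""Calibration and classification models plus evaluation statistics.

Regression: PLSR (latent variables by minimum cross-validated PRESS),
RBF-kernel SVR (grid-searched), and an extreme learning machine (random
hidden layer, pseudo-inverse readout, grid-searched). Classification:
PLS-DA (one-hot PLS regression with argmax decoding, latent variables by
maximum cross-validated accuracy).

Metrics follow the usual chemometric conventions: R2 = 1 - SSres/SStot,
rRMSE = 100*RMSE/mean(reference of the evaluated subset), and
RPD = sd(reference of the subset)/RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import confusion_matrix, f1_score, precision_score, recall_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVR

__all__ = [
    "PLSRModel",
    "PLSDAModel",
    "SVRModel",
    "ELMModel",
    "plsr_fit",
    "plsda_fit",
    "svr_fit",
    "elm_fit",
    "regression_metrics",
    "classification_metrics",
    "paired_consistency_ttest",
    "residual_summary",
]


def _kfold_indices(n: int, folds: int, seed: int):
    if folds > n:
        raise ValueError(f"fold count {folds} exceeds sample count {n}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _max_components(n: int, p: int, requested: int) -> int:
    return max(1, min(requested, n - 1, p))


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    pls: PLSRegression
    n_components: int
    press_by_lv: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.pls.predict(np.asarray(X, float))).ravel()


def plsr_fit(
    X: np.ndarray, y: np.ndarray, max_lv: int = 15, folds: int = 10, seed: int = 0
) -> PLSRModel:
    """PLS regression with the latent-variable count chosen by minimum
    cross-validated PRESS."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    n, p = X.shape
    max_lv = _max_components(n, p, max_lv)
    splits = _kfold_indices(n, folds, seed)
    press = {}
    for lv in range(1, max_lv + 1):
        sse = 0.0
        ok = True
        for tr, te in splits:
            lv_eff = _max_components(len(tr), p, lv)
            if lv_eff < lv:
                ok = False
                break
            m = PLSRegression(n_components=lv, scale=False).fit(X[tr], y[tr])
            resid = y[te] - m.predict(X[te]).ravel()
            sse += float(resid @ resid)
        if ok:
            press[lv] = sse
    best = min(press, key=lambda lv: (press[lv], lv))
    pls = PLSRegression(n_components=best, scale=False).fit(X, y)
    return PLSRModel(pls=pls, n_components=best, press_by_lv=press)


def plsr_cv_rmse(
    X: np.ndarray, y: np.ndarray, max_lv: int = 15, folds: int = 10, seed: int = 0
) -> float:
    """RMSECV of a PLSR model at its PRESS-optimal latent-variable count
    (pooled over held-out folds)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    model = plsr_fit(X, y, max_lv=max_lv, folds=folds, seed=seed)
    return float(np.sqrt(model.press_by_lv[model.n_components] / len(y)))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    pls: PLSRegression
    classes: np.ndarray
    n_components: int
    acc_by_lv: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.asarray(self.pls.predict(np.asarray(X, float)))
        return self.classes[np.argmax(scores, axis=1)]


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y


def plsda_fit(
    X: np.ndarray,
    labels: np.ndarray,
    max_lv: int = 15,
    folds: int = 10,
    seed: int = 0,
) -> PLSDAModel:
    """One-hot PLS regression; predicted class = argmax of predicted scores;
    latent variables chosen by maximum cross-validated accuracy (ties go to
    fewer components)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n, p = X.shape
    Y = _one_hot(labels, classes)
    max_lv = _max_components(n, p, max_lv)
    folds = min(folds, int(np.min(np.bincount(np.searchsorted(classes, labels)))))
    folds = max(folds, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, labels))
    for tr, _ in splits:
        if len(np.unique(labels[tr])) < len(classes):
            raise ValueError("a class is absent from a training fold")
    acc = {}
    for lv in range(1, max_lv + 1):
        correct = 0
        ok = True
        for tr, te in splits:
            if lv > _max_components(len(tr), p, lv):
                ok = False
                break
            m = PLSRegression(n_components=lv, scale=False).fit(X[tr], Y[tr])
            pred = classes[np.argmax(m.predict(X[te]), axis=1)]
            correct += int(np.sum(pred == labels[te]))
        if ok:
            acc[lv] = correct / n
    best = max(acc, key=lambda lv: (acc[lv], -lv))
    pls = PLSRegression(n_components=best, scale=False).fit(X, Y)
    return PLSDAModel(pls=pls, classes=classes, n_components=best, acc_by_lv=acc)


def plsda_cv_metrics(
    X: np.ndarray,
    labels: np.ndarray,
    max_lv: int = 15,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Pooled cross-validated accuracy / macro precision / macro recall (in
    percent) of a PLS-DA model at its accuracy-optimal component count."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    model = plsda_fit(X, labels, max_lv=max_lv, folds=folds, seed=seed)
    classes = model.classes
    n, p = X.shape
    folds_eff = min(folds, int(np.min(np.bincount(np.searchsorted(classes, labels)))))
    folds_eff = max(folds_eff, 2)
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    Y = _one_hot(labels, classes)
    pred = np.empty(n, dtype=labels.dtype)
    for tr, te in skf.split(X, labels):
        lv = _max_components(len(tr), p, model.n_components)
        m = PLSRegression(n_components=lv, scale=False).fit(X[tr], Y[tr])
        pred[te] = classes[np.argmax(m.predict(X[te]), axis=1)]
    return {
        "acccv": 100.0 * float(np.mean(pred == labels)),
        "precisioncv": 100.0 * float(
            precision_score(labels, pred, average="macro", zero_division=0)
        ),
        "recallcv": 100.0 * float(
            recall_score(labels, pred, average="macro", zero_division=0)
        ),
    }


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------


def default_svr_grid() -> dict:
    return {
        "C": [2.0**e for e in range(-5, 16, 2)],
        "gamma": [2.0**e for e in range(-15, 4, 2)],
        "epsilon": [0.01, 0.05, 0.1],
    }


@dataclass
class SVRModel:
    svr: SVR
    mean: np.ndarray
    sd: np.ndarray
    best_params: dict
    cv_rmse: float

    def predict(self, F: np.ndarray) -> np.ndarray:
        Z = (np.asarray(F, float) - self.mean) / self.sd
        return self.svr.predict(Z)


def svr_fit(
    F: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SVRModel:
    """RBF-kernel epsilon-SVR; (C, gamma, epsilon) by grid search minimizing
    cross-validated RMSE. Features are standardized with training statistics."""
    F = np.asarray(F, float)
    y = np.asarray(y, float).ravel()
    grid = grid if grid is not None else default_svr_grid()
    if not all(grid.get(k) for k in ("C", "gamma", "epsilon")):
        raise ValueError("grid must provide nonempty C, gamma and epsilon lists")
    mean = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (F - mean) / sd
    splits = _kfold_indices(len(y), folds, seed)
    best = None
    for C in grid["C"]:
        for gamma in grid["gamma"]:
            for eps in grid["epsilon"]:
                sse = 0.0
                for tr, te in splits:
                    m = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
                    m.fit(Z[tr], y[tr])
                    r = y[te] - m.predict(Z[te])
                    sse += float(r @ r)
                rmse = np.sqrt(sse / len(y))
                key = (rmse, C, gamma, eps)
                if best is None or key < best[0]:
                    best = (key, dict(C=C, gamma=gamma, epsilon=eps))
    params = best[1]
    svr = SVR(kernel="rbf", **params).fit(Z, y)
    return SVRModel(svr=svr, mean=mean, sd=sd, best_params=params, cv_rmse=best[0][0])


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------


def _elm_hidden(F, W, b, activation):
    H = F @ W.T + b
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-H))
    if activation == "identity":
        return H
    raise ValueError(f"unknown activation {activation!r}")


@dataclass
class ELMModel:
    W: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    activation: str
    mean: np.ndarray
    sd: np.ndarray
    best_params: dict

    def predict(self, F: np.ndarray) -> np.ndarray:
        Z = (np.asarray(F, float) - self.mean) / self.sd
        H = _elm_hidden(Z, self.W, self.b, self.activation)
        return np.hstack([H, np.ones((len(H), 1))]) @ self.beta


def default_elm_grid() -> dict:
    return {
        "hidden_units": [20, 50, 100, 200],
        "weight_range": [0.1, 0.5, 1.0],
        "bias_range": [0.1, 0.5, 1.0],
    }


def _elm_weights(max_hidden: int, d: int, weight_range: float, bias_range: float, seed: int):
    # one draw at the largest width; smaller widths take a prefix, so the
    # hidden bases are nested across the grid's hidden_units values
    rng = np.random.default_rng(seed)
    W = rng.uniform(-weight_range, weight_range, size=(max_hidden, d))
    b = rng.uniform(-bias_range, bias_range, size=max_hidden)
    return W, b


def elm_fit(
    F: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    activation: str = "sigmoid",
) -> ELMModel:
    """Extreme learning machine: random input weights/biases (uniform in the
    grid's ranges, seeded), sigmoid hidden layer, output weights by
    Moore-Penrose pseudo-inverse; grid point chosen by cross-validated RMSE."""
    F = np.asarray(F, float)
    y = np.asarray(y, float).ravel()
    grid = grid if grid is not None else default_elm_grid()
    hidden_list = sorted(grid["hidden_units"])
    if min(hidden_list) < 1:
        raise ValueError("hidden unit counts must be >= 1")
    mean = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (F - mean) / sd
    d = Z.shape[1]
    splits = _kfold_indices(len(y), folds, seed)
    max_hidden = max(hidden_list)
    best = None
    for wr in grid["weight_range"]:
        for br in grid["bias_range"]:
            W_full, b_full = _elm_weights(max_hidden, d, wr, br, seed)
            for h in hidden_list:
                W, b = W_full[:h], b_full[:h]
                sse = 0.0
                for tr, te in splits:
                    H_tr = _elm_hidden(Z[tr], W, b, activation)
                    H_tr = np.hstack([H_tr, np.ones((len(tr), 1))])
                    beta = np.linalg.pinv(H_tr) @ y[tr]
                    H_te = _elm_hidden(Z[te], W, b, activation)
                    H_te = np.hstack([H_te, np.ones((len(te), 1))])
                    r = y[te] - H_te @ beta
                    sse += float(r @ r)
                rmse = np.sqrt(sse / len(y))
                key = (rmse, h, wr, br)
                if best is None or key < best[0]:
                    best = (key, dict(hidden_units=h, weight_range=wr, bias_range=br))
    params = best[1]
    W_full, b_full = _elm_weights(
        max_hidden, d, params["weight_range"], params["bias_range"], seed
    )
    W, b = W_full[: params["hidden_units"]], b_full[: params["hidden_units"]]
    H = _elm_hidden(Z, W, b, activation)
    beta = np.linalg.pinv(np.hstack([H, np.ones((len(H), 1))])) @ y
    return ELMModel(
        W=W, b=b, beta=beta, activation=activation, mean=mean, sd=sd, best_params=params
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def regression_metrics(
    y_ref: np.ndarray, y_pred: np.ndarray, subsets: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-subset R2, RMSE, rRMSE (%) and RPD; each subset is evaluated
    strictly on its own indices."""
    y_ref = np.asarray(y_ref, float)
    y_pred = np.asarray(y_pred, float)
    rows = {}
    for name, idx in subsets.items():
        idx = np.asarray(idx, int)
        if idx.size == 0:
            raise ValueError(f"subset {name!r} is empty")
        yr, yp = y_ref[idx], y_pred[idx]
        if np.mean(yr) == 0:
            raise ValueError(f"subset {name!r} has zero mean reference: rRMSE undefined")
        resid = yr - yp
        rmse = float(np.sqrt(np.mean(resid**2)))
        sstot = float(np.sum((yr - yr.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sstot if sstot > 0 else np.nan
        sd = float(np.std(yr, ddof=1)) if idx.size > 1 else np.nan
        rows[name] = {
            "n": idx.size,
            "R2": r2,
            "RMSE": rmse,
            "rRMSE": 100.0 * rmse / float(np.mean(yr)),
            "RPD": sd / rmse if rmse > 0 else np.inf,
        }
    return pd.DataFrame(rows).T


def classification_metrics(
    labels_ref: np.ndarray, labels_pred: np.ndarray, subsets: dict[str, np.ndarray]
) -> dict[str, dict]:
    """Per-subset ACC, macro precision/recall, macro F1 and weighted F1 (all
    in percent) plus the confusion matrix."""
    labels_ref = np.asarray(labels_ref)
    labels_pred = np.asarray(labels_pred)
    vocab = np.unique(labels_ref)
    unseen = set(np.unique(labels_pred)) - set(vocab)
    if unseen:
        raise ValueError(f"predicted label(s) outside reference vocabulary: {sorted(unseen)}")
    out = {}
    for name, idx in subsets.items():
        idx = np.asarray(idx, int)
        yr, yp = labels_ref[idx], labels_pred[idx]
        cm = confusion_matrix(yr, yp, labels=vocab)
        out[name] = {
            "ACC": 100.0 * float(np.trace(cm)) / float(cm.sum()),
            "Precision": 100.0 * float(
                precision_score(yr, yp, labels=vocab, average="macro", zero_division=0)
            ),
            "Recall": 100.0 * float(
                recall_score(yr, yp, labels=vocab, average="macro", zero_division=0)
            ),
            "MF1": 100.0 * float(
                f1_score(yr, yp, labels=vocab, average="macro", zero_division=0)
            ),
            "WF1": 100.0 * float(
                f1_score(yr, yp, labels=vocab, average="weighted", zero_division=0)
            ),
            "confusion": pd.DataFrame(cm, index=vocab, columns=vocab),
        }
    return out


def paired_consistency_ttest(
    y_ref: np.ndarray, y_pred: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-tailed paired t-test on prediction-reference differences.

    Returns (reject flag, p-value); identical vectors give statistic 0 and
    p = 1 (no rejection).
    """
    y_ref = np.asarray(y_ref, float)
    y_pred = np.asarray(y_pred, float)
    if y_ref.shape != y_pred.shape or y_ref.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    d = y_pred - y_ref
    if np.allclose(d, 0):
        return False, 1.0
    t, p = stats.ttest_rel(y_pred, y_ref)
    return bool(p < alpha), float(p)


def residual_summary(
    y_ref: np.ndarray, y_pred: np.ndarray, threshold: float
) -> dict:
    """Residual (prediction minus reference) range, share within +/-threshold
    and the empirical central 95% interval."""
    resid = np.asarray(y_pred, float) - np.asarray(y_ref, float)
    if resid.size == 0:
        raise ValueError("empty input")
    lo, hi = np.percentile(resid, [2.5, 97.5])
    return {
        "min": float(resid.min()),
        "max": float(resid.max()),
        "share_within": 100.0 * float(np.mean(np.abs(resid) <= threshold)),
        "interval95": (float(lo), float(hi)),
    }
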