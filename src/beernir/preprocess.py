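"""Spectral preprocessing operators and data-driven method selection.

Operators: Savitzky-Golay smoothing (SG), multiplicative scatter correction
(MSC), standard normal variate (SNV), wavelet denoising (WD) and Fourier
transform denoising (FTD); chains of operators are expressed as a
``PreprocessSpec``. ``select_preprocessing`` ranks candidate chains by
10-fold cross-validated PLSR (regression) or PLS-DA (classification)
performance on the calibration set only.

All operators are shape preserving (N x P in, N x P out) and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import savgol_filter

from .chemometric_models import plsr_cv_rmse, plsda_cv_metrics, plsr_fit

OPERATORS = ("SG", "MSC", "SNV", "WD", "FTD")

# shipped defaults: the winning chains per task in the reference workflow
# (re-derivable from data via select_preprocessing)
DEFAULT_SPEC_BY_TASK = {
    "alcohol": "wd",
    "wort": "snv",
    "classification": "wd+ft",
}


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered operator chain; each step is (name, params dict)."""

    steps: tuple = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a preprocessing spec needs at least one step")
        for op, _ in self.steps:
            if op not in OPERATORS:
                raise ValueError(f"unknown operator {op!r}; choose from {OPERATORS}")
        if not self.name:
            object.__setattr__(
                self, "name", "+".join(op.lower() for op, _ in self.steps)
            )

    @classmethod
    def parse(cls, text: str) -> "PreprocessSpec":
        """Parse e.g. 'snv', 'wd+ft', 'sg' into a spec with default params.
        'raw' yields an identity (window-1 SG) chain."""
        alias = {
            "sg": ("SG", {}),
            "msc": ("MSC", {}),
            "snv": ("SNV", {}),
            "wd": ("WD", {}),
            "ft": ("FTD", {}),
            "ftd": ("FTD", {}),
            "raw": ("SG", {"window": 1, "polyorder": 0}),
        }
        steps = []
        for token in text.lower().split("+"):
            token = token.strip()
            if token not in alias:
                raise ValueError(f"unknown preprocessing token {token!r}")
            steps.append(alias[token])
        return cls(steps=tuple(steps), name=text.lower())


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centred and scaled to unit sample
    (n-1) standard deviation."""
    X = np.asarray(X, float)
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant row {int(bad[0])}: SNV undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction: per row fit x = a*ref + b by least
    squares and return (x - b)/a. Default reference is the column mean of X
    (pass the calibration mean explicitly to avoid leakage across subsets)."""
    X = np.asarray(X, float)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if np.std(ref) == 0:
        raise ValueError("MSC reference has zero variance")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    out = np.empty_like(X)
    for i, x in enumerate(X):
        a = float(rc @ (x - x.mean())) / denom
        if a == 0:
            raise ValueError(f"row {i}: fitted scatter slope is zero")
        b = x.mean() - a * ref.mean()
        out[i] = (x - b) / a
    return out


def sg_smooth(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with polynomial edge handling; window must be
    odd. window=1 is the identity."""
    X = np.asarray(X, float)
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window == 1:
        return X.copy()
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > X.shape[1]:
        raise ValueError("window exceeds the number of wavelengths")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="interp")


def wavelet_denoise(
    X: np.ndarray, wavelet: str = "db4", level: int = 3, rule: str = "soft-universal"
) -> np.ndarray:
    """Wavelet denoising: decompose each row, soft-threshold the detail
    coefficients with the universal threshold estimated from the median
    absolute deviation of the finest level, reconstruct to length P."""
    X = np.asarray(X, float)
    if rule != "soft-universal":
        raise ValueError(f"unknown thresholding rule {rule!r}")
    p = X.shape[1]
    max_level = pywt.dwt_max_level(p, pywt.Wavelet(wavelet).dec_len)
    if level < 1 or level > max_level:
        raise ValueError(f"level {level} infeasible for {p} points (max {max_level})")
    out = np.empty_like(X)
    for i, x in enumerate(X):
        coeffs = pywt.wavedec(x, wavelet, level=level)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(p))
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
        out[i] = pywt.waverec(coeffs, wavelet)[:p]
    return out


def fourier_denoise(X: np.ndarray, keep_fraction: float = 0.1) -> np.ndarray:
    """Fourier denoising: real FFT per row, zero every frequency bin above
    ceil(keep_fraction * n_bins), inverse transform."""
    X = np.asarray(X, float)
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    p = X.shape[1]
    spec = np.fft.rfft(X, axis=1)
    n_bins = spec.shape[1]
    keep = int(np.ceil(keep_fraction * n_bins))
    spec[:, keep:] = 0.0
    return np.fft.irfft(spec, n=p, axis=1)


_DISPATCH = {
    "SG": sg_smooth,
    "MSC": msc,
    "SNV": snv,
    "WD": wavelet_denoise,
    "FTD": fourier_denoise,
}


def apply_spec(
    X: np.ndarray, spec: PreprocessSpec, msc_reference: np.ndarray | None = None
) -> np.ndarray:
    """Apply an operator chain in order. An MSC step uses ``msc_reference``
    when given (the calibration mean in a leakage-safe pipeline)."""
    out = np.asarray(X, float)
    for op, params in spec.steps:
        if op == "MSC":
            out = msc(out, reference=msc_reference, **params)
        else:
            out = _DISPATCH[op](out, **params)
    return out


def select_preprocessing(
    candidates: list[PreprocessSpec],
    X_cal: np.ndarray,
    y: np.ndarray,
    task: str,
    folds: int = 10,
    seed: int = 0,
    max_lv: int = 15,
) -> pd.DataFrame:
    """Rank candidate chains by seeded 10-fold cross-validation on the
    calibration data: PLSR RMSECV (ascending, secondary RPD_CV descending)
    for regression, PLS-DA ACCCV (descending, secondary PrecisionCV) for
    classification. Ties beyond the secondary metric keep candidate order."""
    if not candidates:
        raise ValueError("need at least one candidate")
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    X_cal = np.asarray(X_cal, float)
    if folds > X_cal.shape[0]:
        raise ValueError("fold count exceeds sample count")
    rows = []
    for order, spec in enumerate(candidates):
        Xp = apply_spec(X_cal, spec)
        if task == "regression":
            rmsecv = plsr_cv_rmse(
                Xp, np.asarray(y, float), max_lv=max_lv, folds=folds, seed=seed
            )
            rpd_cv = float(np.std(np.asarray(y, float), ddof=1)) / rmsecv
            rows.append(
                dict(candidate=spec.name, order=order, RMSECV=rmsecv, RPD_CV=rpd_cv)
            )
        else:
            m = plsda_cv_metrics(
                Xp, np.asarray(y), max_lv=max_lv, folds=folds, seed=seed
            )
            rows.append(
                dict(
                    candidate=spec.name,
                    order=order,
                    ACCCV=m["acccv"],
                    PrecisionCV=m["precisioncv"],
                    RecallCV=m["recallcv"],
                )
            )
    df = pd.DataFrame(rows)
    if task == "regression":
        df = df.sort_values(
            ["RMSECV", "RPD_CV", "order"], ascending=[True, False, True]
        )
    else:
        df = df.sort_values(
            ["ACCCV", "PrecisionCV", "order"], ascending=[False, False, True]
        )
    return df.reset_index(drop=True)
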