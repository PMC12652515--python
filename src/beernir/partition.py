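"""Dataset partitioning: random external test holdout followed by an SPXY
(joint X-Y Kennard-Stone) calibration/validation split, at a 2:1:1 ratio,
plus per-subset summary statistics.

SPXY greedily selects samples by max-min distance under
d(i, j) = d_x(i, j)/max d_x + d_y(i, j)/max d_y (Euclidean in both blocks);
distance ties are broken toward the smallest candidate index, making the
split a pure function of (X, y, n_cal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometric_models import _one_hot  # shared one-hot encoding


@dataclass(frozen=True)
class PartitionIndices:
    """Disjoint calibration/validation/test index sets over 0..N-1."""

    cal: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cal", "val", "test"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=int)
            )
        all_idx = np.concatenate([self.cal, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("partition subsets overlap")
        if not np.array_equal(np.sort(all_idx), np.arange(len(all_idx))):
            raise ValueError("partition does not cover 0..N-1 exactly")

    @property
    def n_total(self) -> int:
        return len(self.cal) + len(self.val) + len(self.test)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cal": self.cal, "val": self.val, "test": self.test}


def random_holdout(
    N: int, n_test: int, seed: int, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform seeded draw of ``n_test`` indices without replacement; returns
    (test_idx, rest_idx), both sorted. With ``labels`` the draw is stratified
    proportionally by class."""
    if not (0 < n_test < N):
        raise ValueError(f"n_test must be in (0, {N})")
    rng = np.random.default_rng(seed)
    if labels is None:
        test = np.sort(rng.choice(N, size=n_test, replace=False))
    else:
        labels = np.asarray(labels)
        picks = []
        classes = np.unique(labels)
        quota = {c: int(round(n_test * np.mean(labels == c))) for c in classes}
        # adjust rounding drift onto the largest class
        drift = n_test - sum(quota.values())
        quota[classes[np.argmax([np.sum(labels == c) for c in classes])]] += drift
        for c in classes:
            pool = np.flatnonzero(labels == c)
            picks.append(rng.choice(pool, size=quota[c], replace=False))
        test = np.sort(np.concatenate(picks))
    rest = np.setdiff1d(np.arange(N), test)
    return test, rest


def _pairwise_sq(M: np.ndarray) -> np.ndarray:
    sq = np.sum(M**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def spxy_distances(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized joint X-Y distance matrix used by the SPXY selection."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    dx = np.sqrt(_pairwise_sq(X))
    dy = np.sqrt(_pairwise_sq(y))
    if dx.max() == 0 or dy.max() == 0:
        raise ValueError("degenerate inputs: all samples identical in X or y")
    return dx / dx.max() + dy / dy.max()


def spxy_split(
    X: np.ndarray, y: np.ndarray, n_cal: int
) -> tuple[np.ndarray, np.ndarray]:
    """Kennard-Stone max-min selection of ``n_cal`` calibration samples under
    the joint X-Y distance; remaining samples form the validation set. For a
    classification response pass one-hot class indicators as ``y``."""
    X = np.asarray(X, float)
    n = X.shape[0]
    if not (2 <= n_cal < n):
        raise ValueError(f"n_cal must be in [2, {n})")
    D = spxy_distances(X, y)
    # first two picks: the pair at maximum distance, ties toward low indices
    flat = np.argmax(D)  # argmax scans row-major, so ties pick smallest (i, j)
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < n_cal:
        d_min = D[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(d_min))]  # argmax ties -> lowest index
        selected.append(pick)
        remaining.remove(pick)
    return np.sort(np.array(selected)), np.sort(np.array(remaining))


def make_partition(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    ratio: tuple[int, int, int] = (2, 1, 1),
    stratify_labels: np.ndarray | None = None,
) -> PartitionIndices:
    """2:1:1 split: random external test holdout (N * test-share), then SPXY
    on the remainder for calibration vs validation."""
    n = np.asarray(X).shape[0]
    total = sum(ratio)
    n_test = int(round(n * ratio[2] / total))
    test, rest = random_holdout(n, n_test, seed, labels=stratify_labels)
    n_cal = int(round(len(rest) * ratio[0] / (ratio[0] + ratio[1])))
    y = np.asarray(y, float)
    y_rest = y[rest] if y.ndim == 1 else y[rest, :]
    cal_rel, val_rel = spxy_split(np.asarray(X, float)[rest], y_rest, n_cal)
    return PartitionIndices(cal=rest[cal_rel], val=rest[val_rel], test=test)


def one_hot_labels(labels: np.ndarray) -> np.ndarray:
    """One-hot class indicator matrix (columns in sorted class order), the
    y-block used for the classification task's SPXY split."""
    labels = np.asarray(labels)
    return _one_hot(labels, np.unique(labels))


def subset_stats(
    partition: PartitionIndices, targets: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-subset, per-target number, mean, max, min, sample sd and CV%
    (100*sd/mean)."""
    rows = []
    for tname, values in targets.items():
        values = np.asarray(values, float)
        for sname, idx in partition.as_dict().items():
            if len(idx) == 0:
                raise ValueError(f"subset {sname!r} is empty")
            v = values[idx]
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            mean = float(np.mean(v))
            rows.append(
                dict(
                    target=tname,
                    subset=sname,
                    number=len(v),
                    mean=mean,
                    max=float(np.max(v)),
                    min=float(np.min(v)),
                    sd=sd,
                    cv_percent=100.0 * sd / mean if mean != 0 else np.nan,
                )
            )
    return pd.DataFrame(rows)
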