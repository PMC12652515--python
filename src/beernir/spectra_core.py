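"""Core domain types and raw-signal utilities for transmission NIR spectra.

The working signal throughout the package is base-10 absorbance
(A = -log10(I/I0)) on a wavelength grid in nm; matrices are oriented rows =
samples, columns = wavelengths, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: default instrument grid: 900-1700 nm, 228 evenly spaced points
DEFAULT_N_WAVELENGTHS = 228
DEFAULT_RANGE_NM = (900.0, 1700.0)

#: class vocabulary for the authenticity task
CLASSES = ("craft", "industrial", "nonfermented")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength grid must be a 1-D vector of length >= 2")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        lo, hi = DEFAULT_RANGE_NM
        return cls(np.linspace(lo, hi, DEFAULT_N_WAVELENGTHS))

    @property
    def n_points(self) -> int:
        return int(self.wavelengths.size)

    def band_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of grid points inside [lo_nm, hi_nm]."""
        w = self.wavelengths
        return (w >= lo_nm) & (w <= hi_nm)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


@dataclass
class SpectraSet:
    """Absorbance matrix plus per-sample reference values.

    Parameters
    ----------
    ids : sample identifiers, unique strings
    X : (N, P) absorbance matrix in AU
    grid : wavelength axis shared by all rows
    alcohol : optional N-vector, %vol
    wort : optional N-vector, original wort concentration in degrees Plato
    klass : optional N-vector of labels in ``CLASSES``
    """

    ids: list
    X: np.ndarray
    grid: WavelengthGrid
    alcohol: np.ndarray | None = None
    wort: np.ndarray | None = None
    klass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x wavelengths)")
        n, p = self.X.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} spectra")
        if p != self.grid.n_points:
            raise ValueError(
                f"X has {p} columns but the grid has {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("absorbance matrix contains non-finite entries")
        for name in ("alcohol", "wort"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} must have length {n}")
                if np.any(v < 0):
                    raise ValueError(f"{name} values must be >= 0")
                setattr(self, name, v)
        if self.klass is not None:
            k = np.asarray(self.klass, dtype=object)
            if k.shape != (n,):
                raise ValueError(f"klass must have length {n}")
            bad = set(k) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown class labels: {sorted(bad)}")
            self.klass = k

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            grid=self.grid,
            alcohol=None if self.alcohol is None else self.alcohol[idx],
            wort=None if self.wort is None else self.wort[idx],
            klass=None if self.klass is None else self.klass[idx],
        )

    def with_X(self, X_new: np.ndarray) -> "SpectraSet":
        """Copy of this set with a replaced (same-shape) absorbance matrix."""
        return SpectraSet(
            ids=list(self.ids),
            X=np.asarray(X_new, dtype=float),
            grid=self.grid,
            alcohol=None if self.alcohol is None else self.alcohol.copy(),
            wort=None if self.wort is None else self.wort.copy(),
            klass=None if self.klass is None else self.klass.copy(),
        )


@dataclass
class ScanTriplet:
    """Three consecutive raw single-scan intensity vectors plus a background.

    A measurement consists of three scans averaged into one raw spectrum; air
    serves as the background reference for the absorbance conversion.
    """

    scans: np.ndarray  # (3, P) raw intensities
    background: np.ndarray  # (P,) reference intensities

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scans.ndim != 2 or self.scans.shape[0] != 3:
            raise ValueError("scans must be a (3, P) array")
        if self.background.shape != (self.scans.shape[1],):
            raise ValueError("background length must match the scan grid")
        if np.any(self.scans <= 0) or np.any(self.background <= 0):
            raise ValueError("all intensities must be > 0 for absorbance conversion")


def absorbance_from_intensity(
    sample_intensity: np.ndarray, background_intensity: np.ndarray
) -> np.ndarray:
    """Convert transmitted intensity to base-10 absorbance, A = -log10(I/I0).

    Both vectors must be strictly positive; a zero or negative entry raises a
    ``ValueError`` naming the first offending index.
    """
    I = np.asarray(sample_intensity, dtype=float)
    I0 = np.asarray(background_intensity, dtype=float)
    if I.shape != I0.shape:
        raise ValueError("sample and background intensity shapes differ")
    for name, v in (("sample", I), ("background", I0)):
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise ValueError(
                f"nonpositive {name} intensity at index {int(bad[0])}"
            )
    return -np.log10(I / I0)


def average_scans(t: ScanTriplet) -> np.ndarray:
    """Arithmetic mean of the three scans, per wavelength."""
    return t.scans.mean(axis=0)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Spectra CSV: first column `sample_id`, remaining columns named by wavelength
# in nm with >= 2 decimals. Targets CSV: sample_id, alcohol_vol_pct,
# wort_degP, class.
# ---------------------------------------------------------------------------

TARGET_COLUMNS = ("sample_id", "alcohol_vol_pct", "wort_degP", "class")


def write_spectra_csv(
    sset: SpectraSet, path: str | Path, targets_path: str | Path | None = None
) -> None:
    """Write the spectra matrix (and optionally the targets table) to CSV."""
    cols = [f"{w:.2f}" for w in sset.grid.wavelengths]
    df = pd.DataFrame(sset.X, columns=cols)
    df.insert(0, "sample_id", sset.ids)
    df.to_csv(path, index=False, float_format="%.12g")
    if targets_path is not None:
        t = pd.DataFrame({"sample_id": sset.ids})
        t["alcohol_vol_pct"] = sset.alcohol if sset.alcohol is not None else np.nan
        t["wort_degP"] = sset.wort if sset.wort is not None else np.nan
        t["class"] = sset.klass if sset.klass is not None else ""
        t.to_csv(targets_path, index=False, float_format="%.12g")


def read_spectra_csv(
    path: str | Path, targets_path: str | Path | None = None
) -> SpectraSet:
    """Read a spectra CSV (and optional targets CSV keyed by sample_id)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError("first column of a spectra CSV must be 'sample_id'")
    ids = df["sample_id"].tolist()
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id(s): {sorted(set(dup))}")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise ValueError(f"non-numeric wavelength column name: {e}") from None
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelength columns are not sorted strictly increasing")
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {int(r)}, column '{body.columns[c]}'"
        )
    X = numeric.to_numpy(dtype=float)
    alcohol = wort = klass = None
    if targets_path is not None:
        t = pd.read_csv(targets_path, dtype={"sample_id": str})
        missing = [c for c in TARGET_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"targets CSV missing column(s): {missing}")
        t = t.set_index("sample_id")
        absent = [i for i in ids if i not in t.index]
        if absent:
            raise ValueError(f"targets file missing sample id(s): {absent}")
        t = t.loc[ids]
        a = pd.to_numeric(t["alcohol_vol_pct"], errors="coerce").to_numpy()
        w = pd.to_numeric(t["wort_degP"], errors="coerce").to_numpy()
        alcohol = None if np.all(np.isnan(a)) else a
        wort = None if np.all(np.isnan(w)) else w
        k = t["class"].astype(str).to_numpy()
        if not np.all((k == "") | (k == "nan")):
            klass = k.astype(object)
    return SpectraSet(
        ids=ids,
        X=X,
        grid=WavelengthGrid(wavelengths),
        alcohol=alcohol,
        wort=wort,
        klass=klass,
    )
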