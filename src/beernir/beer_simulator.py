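"""Synthetic beer spectrum simulator.

Generates transmission-NIR absorbance spectra with the statistical structure
the analysis pipeline assumes: ethanol C-H/O-H overtone bands whose intensity
scales with alcohol content, sugar/organic-acid bands scaling with original
wort concentration, an amino-acid/protein band (1463-1530 nm) whose strength
separates craft, industrial and non-fermented products, plus baseline drift,
multiplicative scatter and additive noise.

Sample inventory emulates the study design: 23 craft styles x 2 batches x 3
bottles (138), 13 industrial styles x 2 x 3 (78), and a non-fermented
formulation cross of 4 alcohol levels x 5 wort levels x 6 replicates (120),
for 336 spectra in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra_core import CLASSES, SpectraSet, WavelengthGrid

# ---------------------------------------------------------------------------
# bands and recipes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band: center/width in nm, strength in AU per
    concentration unit of the owning component."""

    center: float
    width: float
    strength: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if not (900.0 <= self.center <= 1700.0):
            raise ValueError("band center must lie within [900, 1700] nm")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.strength * np.exp(
            -((wavelengths - self.center) ** 2) / (2.0 * self.width**2)
        )


def default_band_library() -> dict[str, list[ComponentBand]]:
    """Band centers chosen inside the assigned NIR ranges: ethanol second
    harmonics at 1120-1220 and 1360-1440 nm plus first harmonic at
    1620-1700 nm; sugar/acid bands in the same three windows; the
    protein/amino band at 1463-1530 nm; a broad water O-H band near 1440 nm.
    Strengths are per concentration unit (%vol for ethanol, degP-derived
    units for sugars/protein)."""
    return {
        "ethanol": [
            ComponentBand(1180.0, 18.0, 0.010),
            ComponentBand(1400.0, 16.0, 0.020),
            ComponentBand(1660.0, 15.0, 0.014),
        ],
        "sugars": [
            ComponentBand(1170.0, 20.0, 0.006),
            ComponentBand(1420.0, 18.0, 0.012),
            ComponentBand(1680.0, 14.0, 0.008),
        ],
        "protein": [
            ComponentBand(1500.0, 16.0, 0.018),
        ],
        "acids": [
            ComponentBand(1430.0, 25.0, 0.004),
        ],
        "water": [
            ComponentBand(1440.0, 55.0, 0.45),
        ],
        # small broad background representing class-specific additives
        # (flavourings, citric acid, bicarbonate in the blended product)
        "additives": [
            ComponentBand(1300.0, 120.0, 0.010),
        ],
    }


#: class-specific protein/amino signal factor: craft is all-malt (rich peptide
#: profile), industrial uses adjuncts (attenuated), the blended non-fermented
#: product carries essentially none.
PROTEIN_FACTOR = {"craft": 1.0, "industrial": 0.45, "nonfermented": 0.0}
#: additive background only present in the blended (non-fermented) product
ADDITIVE_LEVEL = {"craft": 0.0, "industrial": 0.0, "nonfermented": 1.0}


@dataclass(frozen=True)
class Recipe:
    """Per-sample composition derived from (alcohol, wort, class)."""

    alcohol: float  # %vol
    wort: float  # degrees Plato
    klass: str
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if self.alcohol < 0 or self.wort < 0:
            raise ValueError("alcohol and wort must be >= 0")


def make_recipe(alcohol: float, wort: float, klass: str) -> Recipe:
    """Map declared (alcohol %vol, wort degP, class) to component
    concentrations. Ethanol tracks alcohol linearly; sugars track wort;
    protein tracks wort scaled by the class factor; acids and water are a
    small constant background; additives mark the blended product."""
    if klass not in CLASSES:
        raise ValueError(f"unknown class {klass!r}")
    conc = {
        "ethanol": float(alcohol),
        "sugars": 0.8 * float(wort),
        "protein": PROTEIN_FACTOR[klass] * 0.35 * float(wort),
        "acids": 1.0,
        "water": 1.0,
        "additives": ADDITIVE_LEVEL[klass],
    }
    return Recipe(float(alcohol), float(wort), klass, conc)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum perturbations: additive white noise (AU), random baseline
    offset and slope (drift), and multiplicative scatter."""

    additive_sd: float = 0.002
    offset_sd: float = 0.01
    slope_sd: float = 1e-5  # AU per nm
    scatter_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("additive_sd", "offset_sd", "slope_sd", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# sample designs
# ---------------------------------------------------------------------------

NONFERMENTED_ALCOHOL_LEVELS = (3.0, 4.0, 5.0, 7.0)
NONFERMENTED_WORT_LEVELS = (8.0, 9.0, 10.0, 11.0, 12.0)
NONFERMENTED_REPLICATES = 6

CRAFT_DEFAULTS = dict(n_styles=23, batches=2, bottles=3)
INDUSTRIAL_DEFAULTS = dict(n_styles=13, batches=2, bottles=3)
#: declared-value ranges used when drawing per-style labels; craft covers the
#: stronger/heavier styles up to 12 %vol / 24 degP, industrial lagers cluster
#: in the light range (these bracket the subset statistics the partition
#: module reports).
CRAFT_ALCOHOL_RANGE = (3.5, 12.0)
CRAFT_WORT_RANGE = (10.0, 24.0)
INDUSTRIAL_ALCOHOL_RANGE = (3.0, 5.0)
INDUSTRIAL_WORT_RANGE = (8.0, 12.0)


def design_nonfermented() -> pd.DataFrame:
    """Full cross of 4 alcohol x 5 wort levels, 6 replicates -> 120 rows."""
    rows = []
    for a in NONFERMENTED_ALCOHOL_LEVELS:
        for w in NONFERMENTED_WORT_LEVELS:
            for r in range(NONFERMENTED_REPLICATES):
                rows.append(
                    dict(alcohol=a, wort=w, klass="nonfermented", style=f"a{a}w{w}", rep=r)
                )
    return pd.DataFrame(rows)


def design_commercial(
    n_styles: int,
    batches: int,
    bottles: int,
    klass: str,
    alcohol_range: tuple[float, float],
    wort_range: tuple[float, float],
    seed: int,
) -> pd.DataFrame:
    """n_styles x batches x bottles rows; each style's declared alcohol/wort
    drawn once (seeded, snapped to 0.1) and shared by all its bottles."""
    if min(n_styles, batches, bottles) <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_styles):
        a = round(float(rng.uniform(*alcohol_range)), 1)
        w = round(float(rng.uniform(*wort_range)), 1)
        for b in range(batches):
            for k in range(bottles):
                rows.append(
                    dict(alcohol=a, wort=w, klass=klass, style=f"{klass}{s}", rep=b * bottles + k)
                )
    return pd.DataFrame(rows)


def default_designs(seed: int = 0) -> pd.DataFrame:
    """The full study inventory: 138 craft + 78 industrial + 120 blended."""
    craft = design_commercial(
        klass="craft",
        alcohol_range=CRAFT_ALCOHOL_RANGE,
        wort_range=CRAFT_WORT_RANGE,
        seed=seed * 2 + 1,
        **CRAFT_DEFAULTS,
    )
    industrial = design_commercial(
        klass="industrial",
        alcohol_range=INDUSTRIAL_ALCOHOL_RANGE,
        wort_range=INDUSTRIAL_WORT_RANGE,
        seed=seed * 2 + 2,
        **INDUSTRIAL_DEFAULTS,
    )
    return pd.concat([craft, industrial, design_nonfermented()], ignore_index=True)


# ---------------------------------------------------------------------------
# spectrum generation
# ---------------------------------------------------------------------------


def clean_spectrum(
    recipe: Recipe,
    grid: WavelengthGrid,
    bands: dict[str, list[ComponentBand]] | None = None,
) -> np.ndarray:
    """Noise-free spectrum: linear in component concentrations."""
    bands = bands if bands is not None else default_band_library()
    w = grid.wavelengths
    A = np.zeros_like(w)
    for comp, comp_bands in bands.items():
        c = recipe.concentrations.get(comp, 0.0)
        if c == 0.0:
            continue
        for b in comp_bands:
            A += c * b.profile(w)
    return A


def simulate_spectrum(
    recipe: Recipe,
    grid: WavelengthGrid,
    bands: dict[str, list[ComponentBand]] | None = None,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One noisy spectrum: A_clean * (1 + scatter) + offset + slope*(lambda -
    mean lambda) + additive noise."""
    rng = rng if rng is not None else np.random.default_rng(0)
    w = grid.wavelengths
    A = clean_spectrum(recipe, grid, bands)
    scatter = rng.normal(0.0, noise.scatter_sd)
    offset = rng.normal(0.0, noise.offset_sd)
    slope = rng.normal(0.0, noise.slope_sd)
    eps = rng.normal(0.0, noise.additive_sd, size=w.size)
    return A * (1.0 + scatter) + offset + slope * (w - w.mean()) + eps


def simulate_dataset(
    designs: pd.DataFrame,
    bands: dict[str, list[ComponentBand]] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SpectraSet:
    """One spectrum per design row; pure function of (designs, bands, noise,
    seed)."""
    grid = grid if grid is not None else WavelengthGrid.default()
    rng = np.random.default_rng(seed)
    X = np.empty((len(designs), grid.n_points))
    ids, alcohol, wort, klass = [], [], [], []
    for i, row in enumerate(designs.itertuples(index=False)):
        r = make_recipe(row.alcohol, row.wort, row.klass)
        X[i] = simulate_spectrum(r, grid, bands, noise, rng)
        ids.append(f"{row.klass}_{i:04d}")
        alcohol.append(r.alcohol)
        wort.append(r.wort)
        klass.append(r.klass)
    return SpectraSet(
        ids=ids,
        X=X,
        grid=grid,
        alcohol=np.array(alcohol),
        wort=np.array(wort),
        klass=np.array(klass, dtype=object),
    )


def simulate_default_dataset(
    seed: int = 0, noise: NoiseModel = NoiseModel()
) -> SpectraSet:
    """The default 336-sample synthetic study dataset."""
    return simulate_dataset(default_designs(seed=seed), noise=noise, seed=seed + 10_000)
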