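"""Synthetic ATR-FTIR spectra of rose oil, its adulterants, and spiked blends.

No public spectral dataset exists for this adulteration problem, so the
package ships a parametric generator that emulates the study design it is
built to analyse: three brands of *Rosa damascena* essential oil (REO1-3)
spiked with palmarosa oil (PEO1-3), geranium oil (GEO1-3) or phenylethyl
alcohol (PEOH) at 0, 2, 4, 8, 16, 32, 64 and 100 % v/v, measured over
4000-600 cm^-1.

Each pure component is a sum of Gaussian/Lorentzian bands.  The rose-oil
band positions are the thirteen absorptions characteristic of its
monoterpene-alcohol chemistry (O-H and C-H stretches, C=C stretch,
C-H bends, C-O stretches); amplitudes and widths are free parameters of
the simulation chosen to resemble typical essential-oil ATR spectra.
Adulterant bands are likewise simulation scaffolding, constrained so that
each adulterant has distinguishing absorption inside its quantification
window: palmarosa's strong C=C stretch near 1672 cm^-1 (geraniol-rich oil),
geranium's C-O stretch near 1170 cm^-1 (citronellol/esters), and
phenylethyl alcohol's monosubstituted-aromatic out-of-plane bands at
746/700 cm^-1 plus aromatic C-H (3029) and ring (1496) modes.

Mixing follows Beer-Lambert volumetric additivity:
``A_mix = (1 - v) A_base + v A_adulterant`` with v the volume fraction.
Brand-to-brand variation is a multiplicative lognormal jitter per band;
instrument noise is i.i.d. Gaussian per point.  Everything is
deterministic in the integer seed.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, GridError
from .spectra import Spectrum

__all__ = [
    "BandSpec",
    "ComponentLibrary",
    "DesignRow",
    "SyntheticDataset",
    "default_grid",
    "default_library",
    "band_profile",
    "component_spectrum",
    "mix_spectra",
    "generate_design",
    "generate_dataset",
    "LEVELS",
    "PAIRINGS",
]

#: Adulteration levels of the study design, % v/v.
LEVELS: tuple[int, ...] = (0, 2, 4, 8, 16, 32, 64, 100)

#: The seven oil-adulterant pairings (adulterant brand, base rose-oil brand).
PAIRINGS: tuple[tuple[str, str], ...] = (
    ("PEO1", "REO1"),
    ("PEO2", "REO2"),
    ("PEO3", "REO3"),
    ("GEO1", "REO1"),
    ("GEO2", "REO2"),
    ("GEO3", "REO3"),
    ("PEOH", "REO1"),
)


def default_grid(high: float = 4000.0, low: float = 600.0, step: float = 2.0) -> np.ndarray:
    """Descending wavenumber grid, default 4000 -> 600 cm^-1 in 2 cm^-1 steps."""
    if step <= 0 or high <= low:
        raise GridError("grid requires high > low and step > 0")
    n = int(round((high - low) / step)) + 1
    return high - step * np.arange(n)


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center (cm^-1), peak amplitude (AU), FWHM (cm^-1)."""

    center: float
    amplitude: float
    fwhm: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.fwhm <= 0:
            raise ValueError(f"band fwhm must be > 0, got {self.fwhm}")
        if not 600.0 <= self.center <= 4000.0:
            raise ValueError(f"band center {self.center} outside 4000-600 cm^-1")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


def band_profile(band: BandSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate one band on a grid; the peak value equals the amplitude."""
    grid = np.asarray(grid, dtype=float)
    d = grid - band.center
    if band.shape == "gaussian":
        return band.amplitude * np.exp(-4.0 * np.log(2.0) * d**2 / band.fwhm**2)
    half = band.fwhm / 2.0
    return band.amplitude * half**2 / (d**2 + half**2)


# Rose-oil band positions are the thirteen characteristic absorptions;
# amplitudes/FWHMs are simulation parameters (strongest bands: the
# methylene C-H stretches and the C-O/C-H fingerprint pair at 1056/1005).
# Widths reflect the blend-broadening of a many-component oil.
_REO_BANDS = [
    (3345, 0.12, 40), (2958, 0.35, 22), (2922, 0.60, 26), (2853, 0.45, 22),
    (1669, 0.25, 29), (1514, 0.10, 19), (1452, 0.35, 26), (1377, 0.30, 22),
    (1260, 0.20, 26), (1234, 0.18, 26), (1056, 0.50, 32), (1005, 0.55, 29),
    (829, 0.20, 22),
]

# Palmarosa oil is geraniol-dominated, so it shares the terpene-alcohol
# backbone bands of rose oil (same positions, different weights); its
# distinguishing feature is the strong C=C stretch at 1672 cm^-1 inside
# the 1700-1600 cm^-1 quantification window.
_PEO_BANDS = [
    (3345, 0.18, 40), (2958, 0.30, 22), (2922, 0.58, 26), (2853, 0.43, 22),
    (1672, 0.55, 29), (1452, 0.33, 26), (1377, 0.28, 22), (1260, 0.15, 26),
    (1234, 0.14, 26), (1056, 0.45, 32), (1005, 0.52, 29), (829, 0.22, 22),
]

# Geranium oil: citronellol/geraniol plus formate esters; same backbone,
# plus an ester C=O near 1724 cm^-1 and the C-O band at 1170 cm^-1 that
# sits inside the 1218-1130 cm^-1 window where rose oil is flat.
_GEO_BANDS = [
    (3345, 0.16, 40), (2958, 0.32, 22), (2922, 0.56, 26), (2853, 0.42, 22),
    (1724, 0.12, 29), (1669, 0.15, 29), (1452, 0.34, 26), (1377, 0.29, 22),
    (1260, 0.18, 26), (1234, 0.16, 26), (1170, 0.40, 32), (1056, 0.42, 32),
    (1005, 0.40, 29), (829, 0.18, 22),
]

# Phenylethyl alcohol is a single pure aromatic compound, spectrally
# alien to the terpene oils; unlike a many-component oil its bands are
# not blend-broadened, so the monosubstituted-ring modes are sharp and
# intense, with the 700 cm^-1 out-of-plane band anchoring the
# 710-690 cm^-1 window.
_PEOH_BANDS = [
    (3330, 0.33, 40), (3085, 0.16, 9), (3062, 0.20, 9), (3029, 0.39, 9),
    (2930, 0.46, 12), (2875, 0.33, 12), (1603, 0.23, 7), (1496, 0.59, 7),
    (1453, 0.52, 9), (1045, 0.85, 12), (746, 0.98, 8), (700, 1.10, 7),
]


@dataclass
class ComponentLibrary:
    """Parametric band models for each pure component plus brand jitter.

    ``brand_jitter_cv`` is the coefficient of variation of the lognormal
    multiplicative factor applied independently to each band amplitude of
    a brand, emulating brand-to-brand spectral differences.
    """

    components: dict[str, list[BandSpec]]
    brand_jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.brand_jitter_cv < 0:
            raise ValueError("brand_jitter_cv must be >= 0")
        for name, bands in self.components.items():
            if not bands:
                raise ValueError(f"component {name!r} has no bands")

    def to_yaml(self, path) -> None:
        doc = {
            "brand_jitter_cv": float(self.brand_jitter_cv),
            "components": {
                name: [
                    {
                        "center": float(b.center),
                        "amplitude": float(b.amplitude),
                        "fwhm": float(b.fwhm),
                        "shape": b.shape,
                    }
                    for b in bands
                ]
                for name, bands in self.components.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ComponentLibrary":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        comps = {
            name: [BandSpec(**b) for b in bands]
            for name, bands in doc["components"].items()
        }
        return cls(comps, float(doc.get("brand_jitter_cv", 0.05)))


def default_library(brand_jitter_cv: float = 0.05) -> ComponentLibrary:
    """The built-in four-component library (REO, PEO, GEO, PEOH)."""
    def mk(rows):
        return [BandSpec(c, a, w) for c, a, w in rows]

    return ComponentLibrary(
        {
            "REO": mk(_REO_BANDS),
            "PEO": mk(_PEO_BANDS),
            "GEO": mk(_GEO_BANDS),
            "PEOH": mk(_PEOH_BANDS),
        },
        brand_jitter_cv=brand_jitter_cv,
    )


def component_spectrum(
    library: ComponentLibrary,
    name: str,
    grid: np.ndarray,
    brand_seed: int | None = None,
) -> Spectrum:
    """Sum of the component's band profiles, optionally brand-jittered.

    With ``brand_seed`` given, each band amplitude is scaled by an
    independent lognormal factor with unit mean and CV equal to the
    library's ``brand_jitter_cv``; the draw is deterministic in the seed.
    """
    if name not in library.components:
        raise KeyError(f"unknown component {name!r}")
    bands = library.components[name]
    factors = np.ones(len(bands))
    if brand_seed is not None and library.brand_jitter_cv > 0:
        cv = library.brand_jitter_cv
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = -0.5 * sigma * sigma  # unit mean
        rng = np.random.default_rng(brand_seed)
        factors = rng.lognormal(mu, sigma, size=len(bands))
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for band, f in zip(bands, factors):
        total += f * band_profile(band, grid)
    return Spectrum(name, grid, total)


def mix_spectra(base: Spectrum, adulterant: Spectrum, level: float) -> Spectrum:
    """Beer-Lambert volumetric blend at ``level`` % v/v adulterant."""
    if base.wavenumbers.shape != adulterant.wavenumbers.shape or not np.array_equal(
        base.wavenumbers, adulterant.wavenumbers
    ):
        raise GridError("base and adulterant spectra are on different grids")
    if not 0.0 <= level <= 100.0:
        raise ValueError(f"level must be in [0, 100] % v/v, got {level}")
    v = level / 100.0
    mixed = (1.0 - v) * base.absorbance + v * adulterant.absorbance
    return Spectrum(base.sample_id, base.wavenumbers.copy(), mixed)


@dataclass(frozen=True)
class DesignRow:
    """One sample of the spiking design.

    ``adulterant`` is ``"none"`` exactly for the unspiked (0 % v/v) rows;
    the sample id still records which calibration series the row belongs
    to (``<adulterant brand>_<base brand>_<level>``).
    """

    sample_id: str
    base_brand: str
    adulterant: str
    level: float

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level {self.level} not in {LEVELS}")
        if (self.adulterant == "none") != (self.level == 0):
            raise ValueError("adulterant must be 'none' iff level == 0")

    @property
    def spiked(self) -> bool:
        """True for intermediate levels (neither pure base nor pure adulterant)."""
        return self.level not in (0, 100)

    @property
    def series(self) -> str:
        """Calibration-series key, e.g. ``PEO1_REO1``."""
        return self.sample_id.rsplit("_", 1)[0]


def generate_design() -> list[DesignRow]:
    """Enumerate the study design: 7 pairings x 8 levels = 56 rows.

    The 42 rows at intermediate levels (2-64 % v/v) are the spiked
    samples; each pairing also contributes its pure base (0 %) and pure
    adulterant (100 %) endpoint.  Deterministic and order-stable.
    """
    rows: list[DesignRow] = []
    for adulterant, base in PAIRINGS:
        for level in LEVELS:
            rows.append(
                DesignRow(
                    sample_id=f"{adulterant}_{base}_{level:03d}",
                    base_brand=base,
                    adulterant="none" if level == 0 else adulterant,
                    level=float(level),
                )
            )
    return rows


@dataclass
class SyntheticDataset:
    """Spectra plus the aligned reference table and the generating seed."""

    spectra: list[Spectrum]
    reference: list[DesignRow]
    seed: int

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.reference):
            raise ValueError("one reference row per spectrum required")
        ids_s = [s.sample_id for s in self.spectra]
        ids_r = [r.sample_id for r in self.reference]
        if ids_s != ids_r:
            raise ValueError("spectra and reference rows must align by sample_id")

    def reference_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.reference],
                "base_brand": [r.base_brand for r in self.reference],
                "adulterant": [r.adulterant for r in self.reference],
                "level": [r.level for r in self.reference],
            }
        )


_TRAILING_DIGITS = re.compile(r"\d+$")


def component_of_brand(brand: str) -> str:
    """Map a brand label to its library component (``GEO2`` -> ``GEO``)."""
    return _TRAILING_DIGITS.sub("", brand)


def _brand_seed(seed: int, brand: str) -> int:
    # stable across processes (no use of Python's randomized hash)
    return zlib.crc32(f"{seed}|{brand}".encode()) & 0x7FFFFFFF


def generate_dataset(
    library: ComponentLibrary,
    design: list[DesignRow],
    noise_sd: float = 0.003,
    baseline_slope: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
    n_replicates: int = 3,
) -> SyntheticDataset:
    """Simulate the whole design on one grid; deterministic in ``seed``.

    Per row: the brand-jittered base and adulterant component spectra are
    blended at the row's level, an optional linear baseline
    ``baseline_slope * (nu - nu_min)`` is added, and i.i.d. Gaussian noise
    is added per point.  ``noise_sd`` (AU) is the single-measurement noise;
    the stored spectrum emulates the average of ``n_replicates`` repeat
    measurements, so its noise standard deviation is
    ``noise_sd / sqrt(n_replicates)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)

    brands = {r.base_brand for r in design} | {
        r.adulterant for r in design if r.adulterant != "none"
    }
    brand_spectra: dict[str, Spectrum] = {}
    for brand in sorted(brands):
        comp = component_of_brand(brand)
        if comp not in library.components:
            raise ConfigError(
                f"design references brand {brand!r} but component {comp!r} "
                "is missing from the library"
            )
        brand_spectra[brand] = component_spectrum(
            library, comp, grid, brand_seed=_brand_seed(seed, brand)
        )

    baseline = baseline_slope * (grid - grid.min())
    effective_sd = noise_sd / np.sqrt(n_replicates)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EC7]))
    spectra: list[Spectrum] = []
    for row in design:
        base = brand_spectra[row.base_brand]
        if row.adulterant == "none":
            mixed = base.absorbance.copy()
        else:
            mixed = mix_spectra(base, brand_spectra[row.adulterant], row.level).absorbance
        noise = rng.normal(0.0, effective_sd, size=grid.size) if noise_sd > 0 else 0.0
        spectra.append(Spectrum(row.sample_id, grid, mixed + baseline + noise))
    return SyntheticDataset(spectra=spectra, reference=list(design), seed=int(seed))
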