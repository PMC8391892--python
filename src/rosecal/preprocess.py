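"""Spectral preprocessing: Savitzky-Golay derivatives and vector normalization.

The derivative is taken with respect to the wavenumber axis (units
AU/cm^-1 per derivative order), so it respects the physical direction of
the descending grid rather than the array index.  Vector normalization
follows the common FTIR-software convention: subtract the mean absorbance
of the selected range, then scale the centered vector to unit Euclidean
norm.

``apply_pipeline`` fixes the order of operations used throughout the
package: derivative on the full grid first (so window edges see real
neighbours), then window extraction, then normalization over the
concatenated windowed points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import GridError, NormalizationError
from .spectra import Spectrum, WavenumberWindow, extract_windows, _shared_grid

__all__ = [
    "PreprocessSpec",
    "savgol_derivative",
    "vector_normalize",
    "apply_pipeline",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing recipe: derivative order, SG parameters, normalization."""

    derivative_order: int = 0
    sg_window: int = 9
    sg_polyorder: int = 3
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        if self.derivative_order > self.sg_polyorder:
            raise ValueError("derivative_order must not exceed sg_polyorder")


#: Named preprocessing variants of the calibration grid.
VARIANTS: dict[str, int] = {
    "raw": 0,
    "first_derivative": 1,
    "second_derivative": 2,
}


def _uniform_step(wavenumbers: np.ndarray) -> float:
    steps = np.diff(wavenumbers)
    mean = steps.mean()
    if np.max(np.abs(steps - mean)) > 1e-6 * abs(mean):
        raise GridError("Savitzky-Golay derivative requires a uniform grid")
    return mean


def savgol_derivative(
    spectrum: Spectrum, order: int, window: int = 9, polyorder: int = 3
) -> Spectrum:
    """Local least-squares polynomial derivative d^order A / d nu^order.

    Edge points use the polynomial fitted to the one-sided truncated
    window (scipy's ``interp`` edge mode).  The grid must be uniformly
    spaced; the descending step is accounted for so the derivative is
    physical, not index-based.
    """
    PreprocessSpec(order, window, polyorder)  # reuse the invariant checks
    if window > len(spectrum):
        raise GridError(
            f"SG window ({window}) exceeds spectrum length ({len(spectrum)})"
        )
    step = _uniform_step(spectrum.wavenumbers)
    values = savgol_filter(
        spectrum.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=order,
        delta=abs(step),
        mode="interp",
    )
    if step < 0 and order % 2 == 1:
        values = -values
    return spectrum.with_absorbance(values)


def _vecnorm(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean()
    norm = np.linalg.norm(centered)
    if norm <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise NormalizationError("cannot vector-normalize a constant spectrum")
    return centered / norm


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Mean-center then scale to unit Euclidean norm (dimensionless output)."""
    return spectrum.with_absorbance(_vecnorm(spectrum.absorbance))


def apply_pipeline(
    spectra: Sequence[Spectrum],
    spec: PreprocessSpec,
    windows: Sequence[WavenumberWindow] | None = None,
) -> pd.DataFrame:
    """Derivative (full grid) -> window extraction -> normalization.

    Returns a samples x points DataFrame; the index holds sample ids in
    input order and the columns the retained wavenumbers (descending).
    """
    _shared_grid(spectra)
    rows: list[np.ndarray] = []
    columns: np.ndarray | None = None
    for s in spectra:
        if spec.derivative_order > 0:
            s = savgol_derivative(
                s, spec.derivative_order, spec.sg_window, spec.sg_polyorder
            )
        if windows:
            s = extract_windows(s, windows)
        values = s.absorbance
        if spec.normalize:
            values = _vecnorm(values)
        rows.append(values)
        columns = s.wavenumbers
    return pd.DataFrame(
        np.vstack(rows), index=[s.sample_id for s in spectra], columns=columns
    )
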