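"""Spectra on wavenumber grids: containers, CSV interchange, windowing.

A mid-infrared absorbance spectrum is a pair of equal-length vectors:
wavenumbers in cm^-1 and absorbance in AU.  The canonical grid order is
descending (4000 -> 600 cm^-1), the convention in which instruments plot
mid-IR spectra; constructors normalize ascending input to it and every
other module assumes it.

The interchange format is a "wide" CSV whose first column is named
``wavenumber`` and whose remaining columns each hold one sample
(header = sample id).  A minimal JCAMP-DX reader covers the common
``##XYDATA=(X++(Y..Y))`` tabular dialect with plain (AFFN) numerals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptySelectionError,
    ExtrapolationError,
    GridError,
    ParseError,
    UnsupportedDialectError,
)

__all__ = [
    "Spectrum",
    "WavenumberWindow",
    "read_spectra_table",
    "write_spectra_table",
    "read_jcamp",
    "resample_to_grid",
    "extract_windows",
]


@dataclass(frozen=True)
class WavenumberWindow:
    """Closed wavenumber interval [low, high] in cm^-1, bounds inclusive."""

    high: float
    low: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise GridError(
                f"window high ({self.high}) must exceed low ({self.low})"
            )

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points falling inside the window."""
        return (wavenumbers >= self.low) & (wavenumbers <= self.high)


@dataclass
class Spectrum:
    """Absorbance values on a strictly descending wavenumber grid.

    Ascending input grids are silently reversed (together with the
    absorbance vector) so that every stored spectrum satisfies the
    canonical descending order.
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise GridError("wavenumbers and absorbance must be 1-D vectors")
        if wn.size != ab.size:
            raise GridError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size < 2:
            raise GridError("a spectrum needs at least 2 points")
        if np.isnan(wn).any() or np.isnan(ab).any():
            raise GridError("NaN values are not allowed in a spectrum")
        steps = np.diff(wn)
        if np.all(steps > 0):  # ascending -> canonical descending
            wn, ab = wn[::-1].copy(), ab[::-1].copy()
        elif not np.all(steps < 0):
            raise GridError("wavenumber grid must be strictly monotonic")
        self.wavenumbers = wn
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray, sample_id: str | None = None) -> "Spectrum":
        """Copy of this spectrum with new absorbance values on the same grid."""
        return Spectrum(
            sample_id if sample_id is not None else self.sample_id,
            self.wavenumbers.copy(),
            np.asarray(absorbance, dtype=float),
        )


def _shared_grid(spectra: Sequence[Spectrum]) -> np.ndarray:
    if not spectra:
        raise GridError("need at least one spectrum")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
            raise GridError(
                f"spectrum {s.sample_id!r} is not on the shared wavenumber grid"
            )
    return grid


def read_spectra_table(path) -> list[Spectrum]:
    """Read a wide CSV (``wavenumber`` + one column per sample).

    The grid is re-ordered to canonical descending order if needed.
    Raises :class:`ParseError` naming the first offending cell for
    non-numeric entries and :class:`GridError` for duplicate wavenumbers
    or fewer than two rows.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError("expected a 'wavenumber' column plus at least one sample column")
    if df.columns[0] != "wavenumber":
        raise ParseError(f"first column must be 'wavenumber', got {df.columns[0]!r}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax())
            raise ParseError(
                f"non-numeric value in column {col!r}, data row {row + 1}"
            )
        numeric[col] = converted
    wn = numeric["wavenumber"].to_numpy()
    if wn.size < 2:
        raise GridError("need at least 2 wavenumber rows")
    if np.unique(wn).size != wn.size:
        raise GridError("duplicate wavenumber values in grid")
    order = np.argsort(wn)[::-1]  # canonical descending
    wn = wn[order]
    return [
        Spectrum(str(col), wn, numeric[col].to_numpy()[order])
        for col in numeric.columns[1:]
    ]


def write_spectra_table(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra sharing one grid as a wide CSV at full float precision."""
    if not spectra:
        raise GridError("cannot write an empty list of spectra")
    grid = _shared_grid(spectra)
    data = {"wavenumber": grid}
    for s in spectra:
        data[s.sample_id] = s.absorbance
    pd.DataFrame(data).to_csv(path, index=False)


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader: ``##XYDATA=(X++(Y..Y))`` with AFFN numerals.

    Each data line is an abscissa value followed by ordinate values at
    uniform x spacing; ``##XFACTOR``/``##YFACTOR`` are applied when present.
    Any other data dialect (ASDF/DIF compression, peak tables) raises
    :class:`UnsupportedDialectError`.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    title = "jcamp"
    xfactor = yfactor = 1.0
    firstx = lastx = npoints = None
    data_lines: list[str] = []
    in_data = False
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("##"):
            in_data = False
            key, _, value = stripped[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "TITLE":
                title = value or title
            elif key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "FIRSTX":
                firstx = float(value)
            elif key == "LASTX":
                lastx = float(value)
            elif key == "NPOINTS":
                npoints = int(float(value))
            elif key == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise UnsupportedDialectError(
                        f"unsupported XYDATA dialect {value!r}"
                    )
                in_data = True
            elif key in {"PEAKTABLE", "XYPOINTS", "DATATABLE"}:
                raise UnsupportedDialectError(f"unsupported data label ##{key}")
        elif in_data and stripped:
            data_lines.append(stripped)
    if not data_lines:
        raise UnsupportedDialectError("no ##XYDATA=(X++(Y..Y)) block found")

    starts: list[float] = []
    ys: list[list[float]] = []
    for ln in data_lines:
        tokens = ln.replace(",", " ").split()
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise UnsupportedDialectError(
                f"non-AFFN numeral in data line {ln!r}"
            ) from exc
        if len(values) < 2:
            raise UnsupportedDialectError(f"data line with no ordinates: {ln!r}")
        starts.append(values[0])
        ys.append(values[1:])

    total = sum(len(row) for row in ys)
    if npoints is not None and npoints != total:
        raise ParseError(f"##NPOINTS={npoints} but {total} ordinates found")
    if firstx is not None and lastx is not None and total > 1:
        dx = (lastx - firstx) / (total - 1)
    elif len(starts) > 1:
        dx = (starts[1] - starts[0]) / len(ys[0])
    else:
        raise UnsupportedDialectError("cannot infer x spacing from a single line")

    x: list[float] = []
    y: list[float] = []
    for start, row in zip(starts, ys):
        for j, val in enumerate(row):
            x.append(start + j * dx)
            y.append(val)
    wn = np.asarray(x) * xfactor
    ab = np.asarray(y) * yfactor
    return Spectrum(title, wn, ab)


def resample_to_grid(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid inside its span."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    lo, hi = spectrum.wavenumbers.min(), spectrum.wavenumbers.max()
    if grid.min() < lo or grid.max() > hi:
        raise ExtrapolationError(
            f"requested grid [{grid.min()}, {grid.max()}] exceeds source span [{lo}, {hi}]"
        )
    asc_x = spectrum.wavenumbers[::-1]
    asc_y = spectrum.absorbance[::-1]
    values = np.interp(grid, asc_x, asc_y)
    return Spectrum(spectrum.sample_id, grid, values)


def extract_windows(
    spectrum: Spectrum, windows: Sequence[WavenumberWindow]
) -> Spectrum:
    """Concatenate the grid points inside each window, high to low.

    Bounds are inclusive on both ends; windows must be pairwise disjoint.
    No interpolation occurs: the output grid is a subset of the input grid.
    """
    if not windows:
        raise EmptySelectionError("no windows given")
    ordered = sorted(windows, key=lambda w: w.high, reverse=True)
    for a, b in zip(ordered, ordered[1:]):
        if b.high >= a.low:
            raise GridError(
                f"windows [{a.low}, {a.high}] and [{b.low}, {b.high}] overlap"
            )
    pieces_wn: list[np.ndarray] = []
    pieces_ab: list[np.ndarray] = []
    for w in ordered:
        m = w.mask(spectrum.wavenumbers)
        if not m.any():
            raise EmptySelectionError(
                f"window [{w.low}, {w.high}] selects no grid points"
            )
        pieces_wn.append(spectrum.wavenumbers[m])
        pieces_ab.append(spectrum.absorbance[m])
    return Spectrum(
        spectrum.sample_id, np.concatenate(pieces_wn), np.concatenate(pieces_ab)
    )
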