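"""Core spectral data containers and transforms.

The whole pipeline works on three containers:

* :class:`Spectrum` — a wavelength-indexed trace (absorbance, fluorescence
  emission, or circular dichroism in millidegrees);
* :class:`EEM` — an excitation x emission fluorescence intensity matrix;
* :class:`TitrationSeries` — fluorescence intensity at a fixed emission
  wavelength versus quencher concentration, at one temperature.

All wavelengths are in nm, concentrations in mol/L, temperatures in K.
Transforms (resampling, Savitzky-Golay derivatives, blank subtraction,
peak finding) return new objects; containers are treated as immutable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .exceptions import DataError, RangeError

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "EEM",
    "TitrationSeries",
    "resample",
    "savgol_second_derivative",
    "subtract_blank",
    "find_peaks",
    "read_spectrum",
    "write_spectrum",
    "read_eem",
    "write_eem",
    "read_titration",
    "write_titration",
]

#: grid step (nm) used when a uniform grid is required internally
UNIFORM_STEP_NM = 0.5


class SpectrumKind(str, enum.Enum):
    ABSORBANCE = "absorbance"
    FLUORESCENCE = "fluorescence"
    CD = "cd"


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single wavelength-indexed trace.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    values
        Intensities: absorbance (AU), fluorescence (a.u.) or CD (mdeg).
    kind
        One of :class:`SpectrumKind` (or its string value).
    meta
        Free-form acquisition metadata; recognised keys include
        ``temperature_K``, ``excitation_nm``, ``path_cm`` and ``label``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths, "wavelengths")
        vals = _as_float_array(self.values, "values")
        if wl.size == 0:
            raise DataError("spectrum must contain at least one point")
        if wl.size != vals.size:
            raise DataError("wavelengths and values must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise DataError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def is_uniform(self) -> bool:
        """True if the wavelength grid is (numerically) evenly spaced."""
        steps = np.diff(self.wavelengths)
        return steps.size == 0 or bool(np.allclose(steps, steps[0], rtol=1e-8, atol=1e-9))

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at one wavelength (must lie in range)."""
        wl = float(wavelength_nm)
        if wl < self.wavelengths[0] or wl > self.wavelengths[-1]:
            raise RangeError(
                f"{wl} nm outside spectrum range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        return float(np.interp(wl, self.wavelengths, self.values))

    def with_values(self, values: np.ndarray, **meta_updates) -> "Spectrum":
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.wavelengths, values, self.kind, meta)


@dataclass(frozen=True)
class EEM:
    """Excitation x emission fluorescence intensity matrix."""

    excitation: np.ndarray  # nm, increasing
    emission: np.ndarray  # nm, increasing
    intensities: np.ndarray  # shape (n_excitation, n_emission)

    def __post_init__(self) -> None:
        ex = _as_float_array(self.excitation, "excitation")
        em = _as_float_array(self.emission, "emission")
        z = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise DataError("EEM axes must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise DataError(
                f"intensity matrix shape {z.shape} does not match axes "
                f"({ex.size}, {em.size})"
            )
        if not np.all(np.isfinite(z)):
            raise DataError("EEM intensities contain non-finite values")
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "intensities", z)

    def peak(self) -> tuple[float, float, float]:
        """(excitation nm, emission nm, intensity) of the global maximum."""
        i, j = np.unravel_index(np.argmax(self.intensities), self.intensities.shape)
        return float(self.excitation[i]), float(self.emission[j]), float(self.intensities[i, j])


@dataclass(frozen=True)
class TitrationSeries:
    """Fluorescence quenching titration at one temperature.

    The first concentration must be exactly 0 and defines F0. Intensities
    are assumed corrected for the inner-filter effect before model fitting.
    """

    concentrations: np.ndarray  # mol/L, nondecreasing, first entry 0
    intensities: np.ndarray  # a.u., all > 0
    temperature: float  # K
    emission_nm: float = 340.0
    excitation_nm: float = 280.0

    def __post_init__(self) -> None:
        conc = _as_float_array(self.concentrations, "concentrations")
        inten = _as_float_array(self.intensities, "intensities")
        if conc.size != inten.size:
            raise DataError("concentrations and intensities must have equal length")
        if conc.size < 2:
            raise DataError("titration needs at least two points")
        if conc[0] != 0.0:
            raise DataError("first concentration must be exactly 0 (defines F0)")
        if np.any(np.diff(conc) < 0):
            raise DataError("concentrations must be nondecreasing")
        if np.any(inten <= 0):
            raise DataError("all intensities must be positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "intensities", inten)

    @property
    def f0(self) -> float:
        return float(self.intensities[0])

    def quenched_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Nonzero-concentration points as ([Q], F)."""
        return self.concentrations[1:], self.intensities[1:]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def resample(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    The grid must lie within the source wavelength range; kind and metadata
    are preserved. Idempotent on the spectrum's own grid.
    """
    grid = _as_float_array(grid, "grid")
    if np.any(np.diff(grid) <= 0):
        raise DataError("target grid must be strictly increasing")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise RangeError(
            f"target grid [{grid[0]}, {grid[-1]}] outside source range [{lo}, {hi}]"
        )
    values = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, values, spectrum.kind, spectrum.meta)


def uniform_grid(spectrum: Spectrum, step_nm: float = UNIFORM_STEP_NM) -> Spectrum:
    """Resample onto a uniform grid with the given step, spanning the source range."""
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    n = int(np.floor((hi - lo) / step_nm)) + 1
    return resample(spectrum, lo + step_nm * np.arange(n))


def savgol_second_derivative(
    spectrum: Spectrum, window_points: int = 21, poly_order: int = 3
) -> Spectrum:
    """Second derivative d2(value)/d(lambda)2 via Savitzky-Golay filtering.

    Requires a uniform wavelength grid (use :func:`resample` or
    :func:`uniform_grid` first). Edge points are evaluated from the
    polynomial fitted to the first/last full window; the convention is
    recorded in ``meta['edge_convention']``.
    """
    if window_points % 2 == 0 or window_points <= poly_order:
        raise DataError("window must be odd and larger than the polynomial order")
    if not spectrum.is_uniform:
        raise DataError("second derivative requires a uniform grid; resample first")
    if len(spectrum) < window_points:
        raise DataError("spectrum shorter than the smoothing window")
    step = float(spectrum.wavelengths[1] - spectrum.wavelengths[0])
    deriv = signal.savgol_filter(
        spectrum.values, window_points, poly_order, deriv=2, delta=step, mode="interp"
    )
    return spectrum.with_values(
        deriv,
        derivative_order=2,
        savgol_window=window_points,
        savgol_poly=poly_order,
        edge_convention="endpoint-window polynomial",
    )


def subtract_blank(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Pointwise ``sample - blank`` on the overlapping wavelength range.

    Both spectra must be of the same kind; the blank is resampled onto the
    sample's grid restricted to the overlap.
    """
    if sample.kind is not blank.kind:
        raise TypeError(
            f"kind mismatch: cannot subtract {blank.kind.value} from {sample.kind.value}"
        )
    lo = max(sample.wavelengths[0], blank.wavelengths[0])
    hi = min(sample.wavelengths[-1], blank.wavelengths[-1])
    if lo > hi:
        raise RangeError("spectra have no overlapping wavelength range")
    mask = (sample.wavelengths >= lo) & (sample.wavelengths <= hi)
    grid = sample.wavelengths[mask]
    if grid.size == 0:
        raise RangeError("no sample grid points inside the overlap")
    blank_vals = np.interp(grid, blank.wavelengths, blank.values)
    return Spectrum(grid, sample.values[mask] - blank_vals, sample.kind, sample.meta)


def find_peaks(
    spectrum: Spectrum,
    min_prominence: float = 0.05,
    invert: bool = False,
) -> list[tuple[float, float]]:
    """Locate local maxima (or minima with ``invert=True``) in a spectrum.

    ``min_prominence`` is a fraction of the full signal span; peaks within
    one grid step of either boundary are discarded (derivative traces carry
    edge artifacts there). Returns ``(wavelength, value)`` pairs sorted by
    wavelength; an empty list is a valid outcome.
    """
    y = -spectrum.values if invert else spectrum.values
    span = float(np.ptp(y))
    if span == 0.0:
        return []
    idx, _ = signal.find_peaks(y, prominence=min_prominence * span)
    idx = idx[(idx >= 1) & (idx <= len(spectrum) - 2)]
    return [(float(spectrum.wavelengths[i]), float(spectrum.values[i])) for i in idx]


def dominant_peak(
    spectrum: Spectrum, min_prominence: float = 0.05, invert: bool = False
) -> tuple[float, float]:
    """The single most intense peak; raises AnalysisError when none exists."""
    from .exceptions import AnalysisError

    peaks = find_peaks(spectrum, min_prominence=min_prominence, invert=invert)
    if not peaks:
        raise AnalysisError("no peak found in spectrum")
    key = (min if invert else max)
    return key(peaks, key=lambda p: p[1])


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def _format_meta(meta: dict) -> str:
    return " ".join(f"{k}={v}" for k, v in meta.items())


def _parse_meta(line: str) -> dict:
    meta: dict = {}
    for token in line.split():
        if "=" not in token:
            continue
        key, raw = token.split("=", 1)
        try:
            meta[key] = float(raw) if "." in raw or "e" in raw.lower() else int(raw)
        except ValueError:
            meta[key] = raw
    return meta


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column delimited text with a ``# key=value`` metadata header."""
    header = f"kind={spectrum.kind.value} " + _format_meta(spectrum.meta)
    data = np.column_stack([spectrum.wavelengths, spectrum.values])
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header=header.strip())


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = _parse_meta(first.lstrip("#").strip())
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    kind = SpectrumKind(meta.pop("kind", "fluorescence"))
    return Spectrum(data[:, 0], data[:, 1], kind, meta)


def write_eem(eem: EEM, path: str | Path) -> None:
    """Delimited grid: first row = emission axis, first column = excitation axis."""
    n_ex, n_em = eem.intensities.shape
    grid = np.zeros((n_ex + 1, n_em + 1))
    grid[0, 1:] = eem.emission
    grid[1:, 0] = eem.excitation
    grid[1:, 1:] = eem.intensities
    np.savetxt(path, grid, fmt="%.6g", delimiter="\t")


def read_eem(path: str | Path) -> EEM:
    grid = np.loadtxt(path, delimiter="\t", ndmin=2)
    return EEM(grid[1:, 0], grid[0, 1:], grid[1:, 1:])


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    """Delimited (conc_M, intensity) table; temperature etc. in the header."""
    header = _format_meta(
        {
            "temperature_K": series.temperature,
            "emission_nm": series.emission_nm,
            "excitation_nm": series.excitation_nm,
        }
    )
    data = np.column_stack([series.concentrations, series.intensities])
    np.savetxt(path, data, fmt="%.8g", delimiter="\t", header=header)


def read_titration(path: str | Path) -> TitrationSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    meta = _parse_meta(first.lstrip("#").strip()) if first.startswith("#") else {}
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    return TitrationSeries(
        data[:, 0],
        data[:, 1],
        temperature=float(meta.get("temperature_K", 298.0)),
        emission_nm=float(meta.get("emission_nm", 340.0)),
        excitation_nm=float(meta.get("excitation_nm", 280.0)),
    )
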