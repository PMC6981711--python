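"""Foerster resonance energy transfer (FRET) distance estimation.

From the quenched donor fluorescence the transfer efficiency is

    E = (F0 - F) / F0 = R0^6 / (R0^6 + r^6)

where R0 is the Foerster distance (50% transfer) and r the actual
donor-acceptor separation. R0 follows from the spectral overlap integral

    J = integral F(lam) eps(lam) lam^4 dlam / integral F(lam) dlam

(F: donor emission, arbitrary units; eps: acceptor molar extinction in
M^-1 cm^-1; lam in nm, so J carries units M^-1 cm^-1 nm^4) through

    R0[Angstrom] = 0.211 * (kappa^2 * n^-4 * phi_D * J)^(1/6)

with kappa^2 the dipole orientation factor, n the refractive index and
phi_D the donor quantum yield. Results are reported in nm. Two validity
flags accompany the distance: the FRET equation is considered reliable
for 0.5*R0 < r < 1.5*R0, and meaningful transfer requires the pair to
sit within 2-8 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .spectra import Spectrum, UNIFORM_STEP_NM, resample

__all__ = [
    "FretResult",
    "transfer_efficiency",
    "overlap_integral",
    "forster_radius",
    "donor_acceptor_distance",
    "compute_fret",
    "KAPPA_SQ_STATIC",
    "KAPPA_SQ_DYNAMIC",
    "DEFAULT_REFRACTIVE_INDEX",
    "DEFAULT_QUANTUM_YIELD",
]

#: orientation factor for static donor/acceptor orientations
KAPPA_SQ_STATIC = 0.476
#: orientation factor for freely tumbling dipoles
KAPPA_SQ_DYNAMIC = 2.0 / 3.0
#: refractive index of the aqueous buffer
DEFAULT_REFRACTIVE_INDEX = 1.336
#: donor (tryptophan) fluorescence quantum yield
DEFAULT_QUANTUM_YIELD = 0.15


@dataclass(frozen=True)
class FretResult:
    efficiency: float  # fraction in [0, 1)
    overlap_J: float  # M^-1 cm^-1 nm^4
    r0_nm: float  # Foerster distance
    r_nm: float  # donor-acceptor distance
    valid_range: bool  # 0.5*R0 < r < 1.5*R0
    proximity: bool  # 2 <= r <= 8 nm
    kappa_sq: float
    refractive_index: float
    quantum_yield: float


def transfer_efficiency(f0: float, f: float) -> float:
    """E = (F0 - F)/F0 from donor intensities without/with acceptor."""
    if f0 <= 0:
        raise DataError("F0 must be positive")
    if f < 0 or f > f0:
        raise DataError("F must satisfy 0 <= F <= F0")
    return (f0 - f) / f0


def overlap_integral(donor_emission: Spectrum, acceptor_absorption: Spectrum) -> float:
    """Spectral overlap J in M^-1 cm^-1 nm^4 by trapezoidal quadrature.

    Both spectra are resampled onto a common uniform 0.5 nm grid spanning
    their wavelength overlap. The acceptor spectrum must hold molar
    extinction values (M^-1 cm^-1). Disjoint spectra give J = 0 with a
    warning rather than an error.
    """
    lo = max(donor_emission.wavelengths[0], acceptor_absorption.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_absorption.wavelengths[-1])
    if hi - lo < UNIFORM_STEP_NM:
        warnings.warn("donor emission and acceptor absorption do not overlap; J = 0")
        return 0.0
    grid = np.arange(lo, hi + UNIFORM_STEP_NM / 2, UNIFORM_STEP_NM)
    grid = grid[grid <= hi]
    f = resample(donor_emission, grid).values
    eps = resample(acceptor_absorption, grid).values
    denom = np.trapezoid(f, grid)
    if denom <= 0:
        warnings.warn("donor emission integrates to zero on the overlap; J = 0")
        return 0.0
    numer = np.trapezoid(f * eps * grid**4, grid)
    return float(numer / denom)


def forster_radius(
    overlap_J: float,
    kappa_sq: float = KAPPA_SQ_STATIC,
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
    quantum_yield: float = DEFAULT_QUANTUM_YIELD,
) -> float:
    """Foerster distance R0 in nm.

    The 0.211 prefactor together with J in M^-1 cm^-1 nm^4 yields R0 in
    Angstrom; the result is converted to nm.
    """
    if overlap_J < 0:
        raise DataError("overlap integral must be nonnegative")
    if not 0 <= kappa_sq <= 4:
        raise DataError("kappa^2 must lie in [0, 4]")
    if not 0 < quantum_yield <= 1:
        raise DataError("quantum yield must lie in (0, 1]")
    if refractive_index < 1:
        raise DataError("refractive index must be >= 1")
    r0_angstrom = 0.211 * (
        kappa_sq * refractive_index**-4 * quantum_yield * overlap_J
    ) ** (1.0 / 6.0)
    return r0_angstrom / 10.0


def donor_acceptor_distance(efficiency: float, r0_nm: float) -> tuple[float, bool, bool]:
    """Solve E = R0^6/(R0^6 + r^6) for r.

    Returns ``(r_nm, valid_range, proximity)``. E = 1 gives r = 0;
    E = 0 signals an effectively infinite distance (raised as DataError,
    since no finite distance exists).
    """
    if r0_nm <= 0:
        raise DataError("R0 must be positive")
    if efficiency <= 0 or efficiency > 1:
        if efficiency == 0:
            raise DataError("E = 0 implies infinite donor-acceptor distance")
        raise DataError("efficiency must lie in (0, 1]")
    if efficiency == 1:
        r = 0.0
    else:
        r = r0_nm * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0)
    valid_range = 0.5 * r0_nm < r < 1.5 * r0_nm
    proximity = 2.0 <= r <= 8.0
    return r, valid_range, proximity


def compute_fret(
    donor_emission: Spectrum,
    acceptor_absorption: Spectrum,
    f0: float,
    f: float,
    kappa_sq: float = KAPPA_SQ_STATIC,
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
    quantum_yield: float = DEFAULT_QUANTUM_YIELD,
) -> FretResult:
    """Full FRET block: efficiency, overlap, R0 and distance with flags."""
    e = transfer_efficiency(f0, f)
    j = overlap_integral(donor_emission, acceptor_absorption)
    r0 = forster_radius(j, kappa_sq, refractive_index, quantum_yield)
    r, valid_range, proximity = donor_acceptor_distance(e, r0)
    return FretResult(
        efficiency=e,
        overlap_J=j,
        r0_nm=r0,
        r_nm=r,
        valid_range=valid_range,
        proximity=proximity,
        kappa_sq=kappa_sq,
        refractive_index=refractive_index,
        quantum_yield=quantum_yield,
    )
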