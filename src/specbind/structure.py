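"""Structural probes: synchronous fluorescence and CD helix content.

Synchronous fluorescence scans excitation and emission together at a
fixed offset delta-lambda; delta = 15 nm isolates the tyrosine
microenvironment, delta = 60 nm the tryptophan one. A red shift of the
synchronous maximum on ligand binding reports increased polarity around
the fluorophore, a blue shift increased hydrophobicity.

Circular dichroism quantifies alpha-helix content from the mean residue
ellipticity at 208 nm:

    MRE = theta_obs / (10 * Cp * n * l)
    helix% = (-MRE_208 - 4000) / (33000 - 4000) * 100

with theta_obs in millidegrees, Cp the molar protein concentration, n
the residue count and l the path length in cm; -33000 and -4000 are the
208 nm MRE of pure alpha-helix and of beta/random-coil structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import DataError, RangeError
from .spectra import EEM, Spectrum, SpectrumKind, dominant_peak

__all__ = [
    "CDResult",
    "ShiftResult",
    "synchronous_spectrum",
    "classify_shift",
    "mean_residue_ellipticity",
    "helix_fraction",
    "helix_from_spectrum",
    "MRE_PURE_HELIX_208",
    "MRE_COIL_208",
]

#: 208 nm mean residue ellipticity of pure alpha-helix (deg cm^2 dmol^-1)
MRE_PURE_HELIX_208 = -33000.0
#: 208 nm MRE of beta-form / random coil
MRE_COIL_208 = -4000.0


@dataclass(frozen=True)
class CDResult:
    mre_208: float  # deg cm^2 dmol^-1
    helix_percent: float  # raw value, possibly outside [0, 100]
    clamped: bool  # True when the raw percentage fell outside [0, 100]


@dataclass(frozen=True)
class ShiftResult:
    delta_nm: float  # peak(perturbed) - peak(reference)
    label: str  # "red" | "blue" | "none"
    reference_peak_nm: float
    perturbed_peak_nm: float


def synchronous_spectrum(eem: EEM, delta_lambda: float) -> Spectrum:
    """Extract the synchronous trace along lambda_em = lambda_ex + delta.

    Intensities are bilinearly interpolated on the EEM grid and indexed
    by excitation wavelength. The diagonal must intersect the EEM domain.
    """
    if delta_lambda <= 0:
        raise DataError("delta_lambda must be positive")
    ex_lo = max(eem.excitation[0], eem.emission[0] - delta_lambda)
    ex_hi = min(eem.excitation[-1], eem.emission[-1] - delta_lambda)
    if ex_lo >= ex_hi:
        raise RangeError(
            f"diagonal em = ex + {delta_lambda} nm does not intersect the EEM domain"
        )
    mask = (eem.excitation >= ex_lo) & (eem.excitation <= ex_hi)
    ex = eem.excitation[mask]
    if ex.size < 2:
        raise RangeError("fewer than two excitation grid points on the diagonal")
    interp = RegularGridInterpolator(
        (eem.excitation, eem.emission), eem.intensities, method="linear"
    )
    vals = interp(np.column_stack([ex, ex + delta_lambda]))
    return Spectrum(
        ex,
        vals,
        SpectrumKind.FLUORESCENCE,
        {"delta_lambda_nm": float(delta_lambda), "axis": "excitation"},
    )


def classify_shift(
    reference: Spectrum, perturbed: Spectrum, tolerance: float = 1.0
) -> ShiftResult:
    """Compare peak positions of two (unimodal) spectra.

    ``delta = peak(perturbed) - peak(reference)``; shifts within the
    tolerance are labelled ``"none"``, positive shifts ``"red"`` and
    negative ``"blue"``. Raises AnalysisError when either spectrum has
    no interior peak.
    """
    ref_peak, _ = dominant_peak(reference)
    pert_peak, _ = dominant_peak(perturbed)
    delta = pert_peak - ref_peak
    if abs(delta) <= tolerance:
        label = "none"
    elif delta > 0:
        label = "red"
    else:
        label = "blue"
    return ShiftResult(delta, label, ref_peak, pert_peak)


def mean_residue_ellipticity(
    theta_obs_mdeg: float, cp_molar: float, n_residues: int, path_cm: float
) -> float:
    """MRE in deg cm^2 dmol^-1 from observed ellipticity in millidegrees."""
    if cp_molar <= 0 or n_residues <= 0 or path_cm <= 0:
        raise DataError("Cp, residue count and path length must be positive")
    return theta_obs_mdeg / (10.0 * cp_molar * n_residues * path_cm)


def helix_fraction(mre_208: float) -> CDResult:
    """Alpha-helix percentage from the 208 nm mean residue ellipticity.

    The affine two-reference formula is applied as-is; values outside
    [0, 100] are reported raw with the ``clamped`` flag set so callers
    can decide how to display them.
    """
    percent = (-mre_208 + MRE_COIL_208) / (-MRE_PURE_HELIX_208 + MRE_COIL_208) * 100.0
    return CDResult(mre_208=mre_208, helix_percent=percent, clamped=not 0 <= percent <= 100)


def helix_from_spectrum(
    cd: Spectrum, cp_molar: float, n_residues: int, path_cm: float
) -> CDResult:
    """Helix content from a CD trace (millidegrees): raw value at 208 nm."""
    if cd.kind is not SpectrumKind.CD:
        raise TypeError("helix content requires a CD spectrum")
    theta_208 = cd.value_at(208.0)
    mre = mean_residue_ellipticity(theta_208, cp_molar, n_residues, path_cm)
    return helix_fraction(mre)
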