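"""Inner-filter correction of measured fluorescence intensities.

When the quencher (or the protein itself) absorbs at the excitation or
emission wavelength, the measured fluorescence underestimates the true
emission. The standard correction multiplies the observed intensity by
the mean attenuation across the cuvette:

    F_cor = F_obs * 10 ** ((A_ex + A_em) / 2)

where A_ex and A_em are the absorbances of the solution at the excitation
and emission wavelengths. A natural-exponent variant
``F_obs * exp((A_ex + A_em) / 2)`` is selectable but not the default; the
base-10 sum form is the one used throughout the absorbance-based
fluorescence literature.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DataError
from .spectra import TitrationSeries

__all__ = ["inner_filter_correct", "correct_titration", "CONVENTIONS"]

CONVENTIONS = ("log10_sum", "exp_sum")


def inner_filter_correct(
    f_obs,
    a_ex,
    a_em,
    convention: str = "log10_sum",
):
    """Correct fluorescence intensity for the inner-filter effect.

    Parameters
    ----------
    f_obs
        Measured fluorescence (scalar or array), a.u., >= 0.
    a_ex, a_em
        Absorbance (AU) at the excitation and emission wavelengths, >= 0.
    convention
        ``"log10_sum"`` (default) for ``F*10^((Aex+Aem)/2)``, or
        ``"exp_sum"`` for ``F*exp((Aex+Aem)/2)``.

    Returns
    -------
    Corrected fluorescence, always >= the observed value.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(~np.isfinite(a_ex)) or np.any(~np.isfinite(a_em)):
        raise DataError("absorbances must be finite")
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise DataError("absorbances must be nonnegative")
    if np.any(f_obs < 0):
        raise DataError("fluorescence intensities must be nonnegative")
    half_sum = (a_ex + a_em) / 2.0
    if convention == "log10_sum":
        factor = 10.0**half_sum
    elif convention == "exp_sum":
        factor = np.exp(half_sum)
    else:
        raise DataError(f"unknown inner-filter convention {convention!r}")
    out = f_obs * factor
    return float(out) if out.ndim == 0 else out


def correct_titration(
    series: TitrationSeries,
    a_ex,
    a_em,
    convention: str = "log10_sum",
) -> TitrationSeries:
    """Apply the inner-filter correction to every point of a titration.

    ``a_ex``/``a_em`` may be scalars or per-point arrays (e.g. quencher
    absorbance increasing along the titration).
    """
    corrected = inner_filter_correct(series.intensities, a_ex, a_em, convention)
    corrected = np.broadcast_to(corrected, series.intensities.shape).copy()
    return TitrationSeries(
        series.concentrations,
        corrected,
        temperature=series.temperature,
        emission_nm=series.emission_nm,
        excitation_nm=series.excitation_nm,
    )
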