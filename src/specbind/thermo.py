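"""Van't Hoff thermodynamics of protein-ligand association.

Binding constants measured at several temperatures are converted to the
standard enthalpy and entropy of association through the linear van't
Hoff relation

    ln K = -dH/(R*T) + dS/R

fitted by ordinary least squares of ln K against 1/T. The Gibbs energy
follows either from dG = dH - T*dS (the default, consistent with the
van't Hoff parameters) or directly from a single constant as
dG = -R*T*ln K. The signs of dH and dS classify the dominant
intermolecular force: positive/positive indicates hydrophobic
(entropy-driven) association, negative/negative hydrogen bonding or van
der Waals contacts, negative/positive electrostatic interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DataError

__all__ = [
    "GAS_CONSTANT",
    "ThermoResult",
    "vant_hoff_fit",
    "gibbs",
    "gibbs_from_K",
    "classify_forces",
    "analyze_thermodynamics",
]

#: gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ThermoResult:
    """Standard thermodynamic parameters of association (J-based units)."""

    delta_H: float  # J/mol
    delta_S: float  # J/(mol*K)
    delta_G_by_T: dict[float, float]  # T (K) -> J/mol, from dH - T*dS
    r_squared: float
    force_class: str
    delta_G_from_K: dict[float, float] = field(default_factory=dict)  # -RT ln K


def vant_hoff_fit(
    k_by_t: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS fit of ln K vs 1/T; returns (delta_H J/mol, delta_S J/(mol*K), r^2).

    With exactly two temperatures the line is exact and r^2 is reported
    as 1. All binding constants must be positive.
    """
    if len(k_by_t) < 2:
        raise DataError("van't Hoff fit needs at least two temperatures")
    T = np.array([t for t, _ in k_by_t], dtype=float)
    K = np.array([k for _, k in k_by_t], dtype=float)
    if np.unique(T).size < 2:
        raise DataError("temperatures must be distinct")
    if np.any(K <= 0) or np.any(T <= 0):
        raise DataError("binding constants and temperatures must be positive")
    log_k = np.log(K)
    res = stats.linregress(1.0 / T, log_k)
    delta_H = -GAS_CONSTANT * res.slope
    delta_S = GAS_CONSTANT * res.intercept
    if T.size == 2 or np.allclose(log_k, log_k[0]):
        r2 = 1.0  # exact line (two points, or zero-slope constant data)
    else:
        r2 = res.rvalue**2
    return float(delta_H), float(delta_S), float(r2)


def gibbs(delta_H: float, delta_S: float, T: float) -> float:
    """Standard Gibbs energy dG = dH - T*dS (J/mol)."""
    if T <= 0:
        raise DataError("temperature must be positive")
    return delta_H - T * delta_S


def gibbs_from_K(K: float, T: float) -> float:
    """Gibbs energy directly from one binding constant: -R*T*ln K (J/mol)."""
    if K <= 0 or T <= 0:
        raise DataError("K and T must be positive")
    return -GAS_CONSTANT * T * float(np.log(K))


def classify_forces(delta_H: float, delta_S: float) -> str:
    """Map the signs of dH and dS onto the dominant interaction force.

    Returns one of ``hydrophobic`` (+,+), ``hbond_vdw`` (-,-),
    ``electrostatic`` (-,+), or ``mixed`` for any other pattern
    (including exact zeros).
    """
    if delta_H > 0 and delta_S > 0:
        return "hydrophobic"
    if delta_H < 0 and delta_S < 0:
        return "hbond_vdw"
    if delta_H < 0 and delta_S > 0:
        return "electrostatic"
    return "mixed"


def analyze_thermodynamics(k_by_t: Sequence[tuple[float, float]]) -> ThermoResult:
    """Full thermodynamic block: van't Hoff fit, dG at each input T, force class."""
    delta_H, delta_S, r2 = vant_hoff_fit(k_by_t)
    dg = {float(t): gibbs(delta_H, delta_S, t) for t, _ in k_by_t}
    dg_k = {float(t): gibbs_from_K(k, t) for t, k in k_by_t}
    return ThermoResult(
        delta_H=delta_H,
        delta_S=delta_S,
        delta_G_by_T=dg,
        r_squared=r2,
        force_class=classify_forces(delta_H, delta_S),
        delta_G_from_K=dg_k,
    )
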