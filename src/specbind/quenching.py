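"""Fluorescence-quenching model fits and mechanism classification.

Three linearized models are fitted by unweighted ordinary least squares,
exactly as practised in steady-state quenching studies:

* Stern-Volmer:            F0/F = 1 + Ksv*[Q]
* modified Stern-Volmer:   F0/(F0-F) = 1/(fa*Ka) * 1/[Q] + 1/fa
* double-log (Hill-type):  log10((F0-F)/F) = log10(Kb) + n*log10([Q])

plus a curvature test on the modified Stern-Volmer plot that detects
biphasic (two site-class) binding, and a rule-based classifier of the
quenching mechanism (static vs. dynamic) from the temperature dependence
of Ksv and the magnitude of the bimolecular quenching rate constant
kq = Ksv/tau0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DataError, FitError
from .spectra import TitrationSeries

__all__ = [
    "SternVolmerResult",
    "ModifiedSVResult",
    "HillBindingResult",
    "BiphasicResult",
    "stern_volmer_fit",
    "modified_sv_fit",
    "detect_biphasic",
    "hill_fit",
    "classify_mechanism",
    "TAU0_BIOPOLYMER_S",
    "KQ_DIFFUSION_LIMIT",
    "DEFAULT_LOW_WINDOW",
    "DEFAULT_HIGH_WINDOW",
]

#: fluorescence lifetime conventionally assigned to biopolymers (s)
TAU0_BIOPOLYMER_S = 1e-8
#: maximum collisional quenching rate constant (M^-1 s^-1); kq far above
#: this value rules out a purely diffusive mechanism
KQ_DIFFUSION_LIMIT = 2e10
#: default concentration windows (mol/L) for biphasic window-wise fits
DEFAULT_LOW_WINDOW = (1e-6, 25e-6)
DEFAULT_HIGH_WINDOW = (15e-6, 80e-6)


@dataclass(frozen=True)
class SternVolmerResult:
    ksv: float  # M^-1
    kq: float  # M^-1 s^-1
    tau0: float  # s
    r_squared: float
    intercept: float
    temperature: float  # K
    degenerate: bool = False

    def __post_init__(self):
        # kq = Ksv / tau0 must hold exactly in every result object
        assert self.kq == self.ksv / self.tau0


@dataclass(frozen=True)
class ModifiedSVResult:
    ka: float  # M^-1, effective quenching constant
    fa: float  # accessible fluorescence fraction (not clamped to [0,1])
    r_squared: float
    window: tuple[float, float]  # mol/L
    temperature: float
    n_points: int


@dataclass(frozen=True)
class HillBindingResult:
    kb: float  # M^-1
    n: float  # binding sites per protein (slope of the double-log plot)
    r_squared: float
    temperature: float


@dataclass(frozen=True)
class BiphasicResult:
    is_biphasic: bool
    low_window: tuple[float, float]
    high_window: tuple[float, float]
    curvature: float  # quadratic coefficient of F0/(F0-F) vs 1/[Q]
    t_statistic: float
    insufficient_points: bool = False


def _ols(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    r2 = 1.0 if np.allclose(y, y[0]) else res.rvalue**2
    return res.slope, res.intercept, r2


def stern_volmer_fit(
    series: TitrationSeries, tau0: float = TAU0_BIOPOLYMER_S
) -> SternVolmerResult:
    """Fit F0/F = 1 + Ksv*[Q] by ordinary least squares.

    The intercept is reported (it should be close to 1 for well-behaved
    data). kq is derived as Ksv/tau0. If no quenching occurred at all the
    result carries ``degenerate=True`` with Ksv = 0.
    """
    q, f = series.quenched_points()
    if q.size < 3:
        raise DataError("Stern-Volmer fit needs at least 3 nonzero-concentration points")
    f0 = series.f0
    if np.allclose(f, f0):
        return SternVolmerResult(0.0, 0.0, tau0, 1.0, 1.0, series.temperature, degenerate=True)
    slope, intercept, r2 = _ols(q, f0 / f)
    return SternVolmerResult(
        ksv=slope,
        kq=slope / tau0,
        tau0=tau0,
        r_squared=r2,
        intercept=intercept,
        temperature=series.temperature,
    )


def _window_points(
    series: TitrationSeries, window: tuple[float, float] | None
) -> tuple[np.ndarray, np.ndarray]:
    q, f = series.quenched_points()
    f0 = series.f0
    keep = q > 0
    if window is not None:
        lo, hi = window
        keep &= (q >= lo * (1 - 1e-12)) & (q <= hi * (1 + 1e-12))
    unquenched = keep & (f >= f0)
    if np.any(unquenched):
        warnings.warn(
            f"dropping {int(unquenched.sum())} point(s) with F >= F0 inside the fit window",
            stacklevel=3,
        )
    keep &= f < f0
    return q[keep], f[keep]


def modified_sv_fit(
    series: TitrationSeries, window: tuple[float, float] | None = None
) -> ModifiedSVResult:
    """Fit the modified Stern-Volmer model on an optional concentration window.

    Regresses F0/(F0-F) on 1/[Q]; the accessible fraction is the reciprocal
    intercept, fa = 1/intercept, and the effective quenching constant is
    Ka = intercept/slope. fa is reported as fitted, never clamped.
    """
    q, f = _window_points(series, window)
    if q.size < 3:
        raise FitError("modified Stern-Volmer fit needs >= 3 quenched points in window")
    f0 = series.f0
    slope, intercept, r2 = _ols(1.0 / q, f0 / (f0 - f))
    if intercept == 0 or slope == 0:
        raise FitError("degenerate modified Stern-Volmer regression")
    actual_window = (float(q.min()), float(q.max())) if window is None else window
    return ModifiedSVResult(
        ka=intercept / slope,
        fa=1.0 / intercept,
        r_squared=r2,
        window=actual_window,
        temperature=series.temperature,
        n_points=int(q.size),
    )


def detect_biphasic(
    series: TitrationSeries,
    t_threshold: float = 2.0,
    low_window: tuple[float, float] = DEFAULT_LOW_WINDOW,
    high_window: tuple[float, float] = DEFAULT_HIGH_WINDOW,
) -> BiphasicResult:
    """Test the modified Stern-Volmer plot for concave-down curvature.

    A quadratic is fitted to F0/(F0-F) vs 1/[Q]; a negative quadratic
    coefficient whose t-statistic exceeds ``t_threshold`` flags biphasic
    (two site-class) binding and the default low/high concentration
    windows are returned for window-wise refits. Single-site data are
    exactly linear in 1/[Q], so the quadratic term vanishes.
    """
    q, f = _window_points(series, None)
    full = (float(q.min()), float(q.max())) if q.size else (0.0, 0.0)
    if q.size < 6:
        return BiphasicResult(
            False, full, full, np.nan, np.nan, insufficient_points=True
        )
    x = 1.0 / q
    y = series.f0 / (series.f0 - f)
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = x.size - 3
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tstat = beta[2] / se[2] if se[2] > 0 else np.inf * np.sign(beta[2] or 1)
    is_biphasic = bool(beta[2] < 0 and abs(tstat) > t_threshold)
    if is_biphasic:
        return BiphasicResult(True, low_window, high_window, float(beta[2]), float(tstat))
    return BiphasicResult(False, full, full, float(beta[2]), float(tstat))


def hill_fit(series: TitrationSeries) -> HillBindingResult:
    """Fit log10((F0-F)/F) = log10(Kb) + n*log10([Q]).

    Points with F >= F0 carry no binding signal on the log scale and are
    dropped with a warning. Returns the binding constant Kb and apparent
    site number n.
    """
    q, f = _window_points(series, None)
    if q.size < 3:
        raise FitError("double-log fit needs >= 3 points with 0 < F < F0")
    f0 = series.f0
    slope, intercept, r2 = _ols(np.log10(q), np.log10((f0 - f) / f))
    return HillBindingResult(
        kb=10.0**intercept, n=slope, r_squared=r2, temperature=series.temperature
    )


def classify_mechanism(
    sv_by_temperature: Sequence[tuple[float, SternVolmerResult]],
    curvature_flag: bool = False,
) -> str:
    """Classify the quenching mechanism from multi-temperature fits.

    Rules
    -----
    * upward Stern-Volmer curvature -> ``"mixed"`` (both mechanisms act);
    * Ksv strictly decreasing with T and every kq above the collisional
      limit (2e10 M^-1 s^-1) -> ``"static"`` (ground-state complex);
    * Ksv strictly increasing with T and kq within the collisional limit
      -> ``"dynamic"``;
    * anything else, or a single temperature -> ``"indeterminate"``.
    """
    if curvature_flag:
        return "mixed"
    if len(sv_by_temperature) < 2:
        return "indeterminate"
    ordered = sorted(sv_by_temperature, key=lambda tr: tr[0])
    ksv = np.array([r.ksv for _, r in ordered])
    kq = np.array([r.kq for _, r in ordered])
    if np.all(np.diff(ksv) < 0) and np.all(kq > KQ_DIFFUSION_LIMIT):
        return "static"
    if np.all(np.diff(ksv) > 0) and np.all(kq <= KQ_DIFFUSION_LIMIT):
        return "dynamic"
    return "indeterminate"
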