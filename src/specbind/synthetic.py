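"""Synthetic instrument data with known ground truth.

No raw spectra accompany the study this package is built around, so every
pipeline stage is exercised against forward-modelled data instead:

* titrations follow the fractional-site quenching model
  ``F = F0 * (1 - sum_i fa_i * K_i[Q] / (1 + K_i[Q]))`` with binding
  constants moved across temperature by the van't Hoff relation;
* excitation-emission matrices are sums of separable Gaussian bands at
  the tryptophan (280/341 nm), tyrosine (275/301 nm) and backbone
  (230/342 nm) positions, attenuated by the bound fraction;
* absorbance spectra carry the protein bands (222/278 nm) and ligand
  bands (207/244 nm), with an optional complexation perturbation that
  shifts and amplifies the 222 nm backbone band;
* CD traces present the double negative band (208/222 nm) scaled so the
  208 nm ellipticity encodes a prescribed alpha-helix percentage.

Noise, where requested, is multiplicative Gaussian on intensities with an
explicit seed; identical seed and config give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigError
from .spectra import EEM, Spectrum, SpectrumKind, TitrationSeries
from .thermo import GAS_CONSTANT

__all__ = [
    "SyntheticConfig",
    "binding_constant_at",
    "generate_titration",
    "generate_sv_titration",
    "generate_hill_titration",
    "generate_eem",
    "generate_absorbance",
    "generate_cd",
    "DEFAULT_CONCENTRATIONS_M",
]

#: titration grid used throughout: 0-80 uM quencher (mol/L)
DEFAULT_CONCENTRATIONS_M = tuple(
    c * 1e-6 for c in (0, 1, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80)
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for the forward models.

    ``sites`` holds (Ka at the reference temperature, accessible fraction)
    pairs; the reference temperature is the first entry of
    ``temperatures``. The default two-site split mirrors a biphasic
    binder with a strong (3.14e4 M^-1) and a weak (4.5e3 M^-1) site
    class. ``delta_H``/``delta_S`` (J/mol, J/mol/K) drive the
    temperature dependence of every site constant.
    """

    sites: tuple[tuple[float, float], ...] = ((3.1419e4, 0.64), (0.45e4, 0.36))
    delta_H: float = 43.4e3
    delta_S: float = 222.0
    f0: float = 1000.0
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_M
    temperatures: tuple[float, ...] = (290.0, 300.0, 310.0)
    noise_sd: float = 0.01
    seed: int = 0
    # CD conversion constants: 4 uM protein, 583 residues, 1 mm path
    cp_molar: float = 4e-6
    n_residues: int = 583
    path_cm: float = 0.1

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 2 or conc[0] != 0.0 or np.any(np.diff(conc) < 0):
            raise ConfigError("concentration grid must be nondecreasing and start at 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not self.sites:
            raise ConfigError("at least one binding site is required")
        fa_total = sum(fa for _, fa in self.sites)
        if fa_total > 1 + 1e-9:
            raise ConfigError(f"accessible fractions sum to {fa_total:.4f} > 1")
        if any(ka < 0 or fa < 0 for ka, fa in self.sites):
            raise ConfigError("site parameters must be nonnegative")

    @property
    def reference_temperature(self) -> float:
        return self.temperatures[0]

    def without_noise(self) -> "SyntheticConfig":
        return replace(self, noise_sd=0.0)


def binding_constant_at(ka_ref: float, config: SyntheticConfig, temperature: float) -> float:
    """Move a reference binding constant to another temperature.

    Uses the van't Hoff relation: ``K(T) = K_ref * exp(-dH/R * (1/T - 1/T_ref))``
    so the generated series is exactly consistent with the fit the
    thermodynamics stage performs.
    """
    t_ref = config.reference_temperature
    return ka_ref * float(
        np.exp(-config.delta_H / GAS_CONSTANT * (1.0 / temperature - 1.0 / t_ref))
    )


def _occupancy(config: SyntheticConfig, conc: np.ndarray, temperature: float) -> np.ndarray:
    """Quenched fraction sum_i fa_i * K_i[Q]/(1 + K_i[Q]) at one temperature."""
    theta = np.zeros_like(conc)
    for ka_ref, fa in config.sites:
        k = binding_constant_at(ka_ref, config, temperature)
        theta += fa * k * conc / (1.0 + k * conc)
    return theta


def _apply_noise(values: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0:
        return values
    noisy = values * (1.0 + sd * rng.standard_normal(values.shape))
    # keep intensities physical: a 1% noise level essentially never clips
    return np.clip(noisy, 1e-12 * np.max(values), None)


def generate_titration(config: SyntheticConfig) -> list[TitrationSeries]:
    """One quenching titration per configured temperature.

    Noiseless output is exactly linear in the modified Stern-Volmer
    coordinates for a single site; every fitting stage recovers the
    generating parameters to machine precision.
    """
    conc = np.asarray(config.concentrations, dtype=float)
    rng = np.random.default_rng(config.seed)
    out = []
    for t in config.temperatures:
        f = config.f0 * (1.0 - _occupancy(config, conc, t))
        f = _apply_noise(f, rng, config.noise_sd)
        out.append(TitrationSeries(conc, f, temperature=t))
    return out


def generate_sv_titration(ksv: float, config: SyntheticConfig, temperature: float | None = None) -> TitrationSeries:
    """Titration obeying the plain Stern-Volmer law F0/F = 1 + Ksv[Q]."""
    conc = np.asarray(config.concentrations, dtype=float)
    t = config.reference_temperature if temperature is None else temperature
    f = config.f0 / (1.0 + ksv * conc)
    rng = np.random.default_rng(config.seed)
    return TitrationSeries(conc, _apply_noise(f, rng, config.noise_sd), temperature=t)


def generate_hill_titration(
    kb: float, n: float, config: SyntheticConfig, temperature: float | None = None
) -> TitrationSeries:
    """Titration obeying the double-log binding law (F0-F)/F = Kb[Q]^n."""
    conc = np.asarray(config.concentrations, dtype=float)
    t = config.reference_temperature if temperature is None else temperature
    with np.errstate(divide="ignore"):
        f = config.f0 / (1.0 + kb * np.power(conc, n, where=conc > 0, out=np.zeros_like(conc)))
    rng = np.random.default_rng(config.seed)
    return TitrationSeries(conc, _apply_noise(f, rng, config.noise_sd), temperature=t)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

# (ex center, em center, amplitude, ex sigma, em sigma), all nm.
# Broad excitation / narrow emission profiles place the synchronous
# delta=15/60 maxima at 301 and 341 nm emission.
EEM_BANDS = (
    (280.0, 341.0, 1.0, 30.0, 4.0),  # tryptophan-like
    (275.0, 301.0, 0.5, 30.0, 4.0),  # tyrosine-like
    (230.0, 342.0, 0.3, 15.0, 6.0),  # polypeptide backbone
)

EEM_EXCITATION = np.arange(200.0, 321.0, 1.0)
EEM_EMISSION = np.arange(285.0, 451.0, 1.0)


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def generate_eem(
    config: SyntheticConfig,
    ligand_conc: float = 0.0,
    bands=EEM_BANDS,
) -> EEM:
    """Excitation-emission matrix, attenuated by the bound fraction.

    ``ligand_conc`` (mol/L) scales all band intensities by
    ``1 - occupancy`` from the titration model at the reference
    temperature, so EEM peak heights track the quenching stage.
    """
    scale = 1.0 - float(
        _occupancy(config, np.array([ligand_conc]), config.reference_temperature)[0]
    )
    z = np.zeros((EEM_EXCITATION.size, EEM_EMISSION.size))
    for ex_c, em_c, amp, ex_s, em_s in bands:
        z += amp * np.outer(
            _gauss(EEM_EXCITATION, ex_c, ex_s), _gauss(EEM_EMISSION, em_c, em_s)
        )
    return EEM(EEM_EXCITATION, EEM_EMISSION, config.f0 * scale * z)


ABSORBANCE_GRID = np.arange(190.0, 320.5, 0.5)
PROTEIN_BANDS = ((222.0, 0.50, 7.0), (278.0, 0.28, 11.0))  # (center, amp, sigma)
LIGAND_BANDS = ((207.0, 0.35, 6.0), (244.0, 0.18, 9.0))


def generate_absorbance(
    config: SyntheticConfig,
    perturb: bool = True,
    shift_nm: float = 2.0,
    gain: float = 1.15,
) -> dict[str, Spectrum]:
    """Protein, ligand and mixture UV absorbance spectra.

    The mixture is ligand + protein; with ``perturb`` enabled the protein
    222 nm backbone band inside the mixture is shifted by ``shift_nm``
    and amplified by ``gain``, emulating ground-state complexation. With
    the perturbation disabled, mixture - ligand equals the protein
    spectrum exactly.
    """
    wl = ABSORBANCE_GRID

    def bands(spec):
        return sum(amp * _gauss(wl, c, s) for c, amp, s in spec)

    protein = bands(PROTEIN_BANDS)
    ligand = bands(LIGAND_BANDS)
    if perturb:
        (c222, a222, s222), rest = PROTEIN_BANDS[0], PROTEIN_BANDS[1:]
        complexed = gain * a222 * _gauss(wl, c222 + shift_nm, s222) + bands(rest)
    else:
        complexed = protein
    mk = lambda v, label: Spectrum(wl, v, SpectrumKind.ABSORBANCE, {"label": label})
    return {
        "protein": mk(protein, "protein"),
        "ligand": mk(ligand, "ligand"),
        "mixture": mk(complexed + ligand, "mixture"),
    }


CD_GRID = np.arange(200.0, 261.0, 1.0)


def generate_cd(helix_percent: float, config: SyntheticConfig) -> Spectrum:
    """CD trace (millidegrees) whose 208 nm band encodes a helix fraction.

    The 208 nm observed ellipticity is set so that converting through the
    mean-residue-ellipticity formula with the config's Cp, residue count
    and path length returns exactly the requested percentage.
    """
    if not 0 <= helix_percent <= 100:
        raise ConfigError("helix_percent must lie in [0, 100]")
    target_mre = -(helix_percent / 100.0 * 29000.0 + 4000.0)
    theta_208 = target_mre * 10.0 * config.cp_molar * config.n_residues * config.path_cm
    shape = -(_gauss(CD_GRID, 208.0, 5.0) + 0.9 * _gauss(CD_GRID, 222.0, 6.0))
    shape_208 = shape[CD_GRID == 208.0][0]
    values = shape * (theta_208 / shape_208)
    return Spectrum(
        CD_GRID,
        values,
        SpectrumKind.CD,
        {
            "cp_molar": config.cp_molar,
            "n_residues": config.n_residues,
            "path_cm": config.path_cm,
            "helix_percent_truth": float(helix_percent),
        },
    )
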