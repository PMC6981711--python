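# specbind

Analysis toolkit for steady-state spectroscopic studies of small-molecule
binding to serum proteins — the workflow used to characterize how a drug
candidate (e.g. an 8-hydroxyquinoline derivative such as cloxyquin) binds
bovine serum albumin (BSA) from fluorescence-quenching titrations, UV-Vis
absorbance, synchronous fluorescence, FRET and circular dichroism.

It is written for pharmacology / biophysics groups who run these
multi-spectroscopic binding panels and want the model fitting, unit
bookkeeping and classification rules in one tested place instead of a
spreadsheet.

## What it computes

Given fluorescence titrations F([Q]) at several temperatures (inner-filter
corrected, `F_cor = F_obs·10^((A_ex+A_em)/2)`):

* **Stern–Volmer**: `F0/F = 1 + K_SV[Q]`, with `k_q = K_SV/τ0`
  (τ0 = 10⁻⁸ s for biopolymers); `k_q ≫ 2×10¹⁰ M⁻¹s⁻¹` together with
  K_SV falling as T rises classifies the quenching as *static*
  (ground-state complex).
* **Modified Stern–Volmer**: `F0/(F0−F) = 1/(f_a·K_a)·1/[Q] + 1/f_a`,
  fitted per concentration window after a curvature test that detects
  biphasic (two site-class) binding.
* **Double-log binding fit**: `log((F0−F)/F) = log K_b + n·log[Q]`.
* **Van't Hoff thermodynamics**: `ln K_b = −ΔH°/RT + ΔS°/R`,
  `ΔG° = ΔH° − TΔS°`, and the sign-table classification of the dominant
  force (ΔH°>0, ΔS°>0 → hydrophobic, etc.).
* **FRET**: `E = (F0−F)/F0 = R0⁶/(R0⁶+r⁶)`, overlap integral
  `J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ`, `R0 = 0.211(κ²n⁻⁴φ_D J)^{1/6}` Å.
* **Structure probes**: synchronous spectra at Δλ = 15/60 nm (Tyr/Trp)
  with red/blue-shift classification, and α-helix content from CD:
  `MRE = θ_obs/(10·C_p·n·l)`, `helix% = (−MRE₂₀₈−4000)/29000·100`.
* **Site-marker displacement**: percent change of K_b in the presence of
  warfarin / ibuprofen / digitoxin probes.

A synthetic-data generator produces titrations, EEMs, absorbance and CD
spectra from known ground truth so the whole pipeline is testable without
instrument output.

## Worked example

```python
from specbind.thermo import vant_hoff_fit, gibbs, classify_forces
from specbind.fret import donor_acceptor_distance

kb_by_t = [(290.0, 0.5506e4), (300.0, 1.3590e4), (310.0, 1.7459e4)]
dH, dS, r2 = vant_hoff_fit(kb_by_t)
print(f"dH = {dH/1e3:.1f} kJ/mol, dS = {dS:.1f} J/mol/K")
print(f"dG(290 K) = {gibbs(dH, dS, 290.0)/1e3:.1f} kJ/mol")
print(f"force class: {classify_forces(dH, dS)}")

r, valid, proximity = donor_acceptor_distance(efficiency=0.19, r0_nm=2.72)
print(f"donor-acceptor distance r = {r:.2f} nm (valid={valid}, 2-8 nm={proximity})")
```

prints

```
dH = 43.4 kJ/mol, dS = 222.0 J/mol/K
dG(290 K) = -21.0 kJ/mol
force class: hydrophobic
donor-acceptor distance r = 3.46 nm (valid=True, 2-8 nm=True)
```

i.e. binding is spontaneous (ΔG° < 0), entropy-driven/hydrophobic
(ΔH°, ΔS° > 0), and the ligand sits ~3.5 nm from the tryptophan donors —
inside the 2–8 nm window where resonance energy transfer is meaningful.

The same analysis runs from the shell:

```bash
specbind simulate --out-dir fixtures --noise-sd 0   # synthetic instrument files
specbind analyze --config config.yaml --data-dir fixtures --out-dir out
specbind cd fixtures/cd.tsv                          # helix content of one CD trace
```

`analyze` writes `report.json` plus TSV tables (Stern–Volmer, modified
Stern–Volmer, binding, site markers) mirroring the usual presentation of
these studies.

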