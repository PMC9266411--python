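# coildyn

Structure and nanosecond dynamics of disordered protein coils from
small-angle scattering (SAXS/SANS) and neutron spin–echo (NSE)
spectroscopy.

Intrinsically disordered proteins (IDPs) behave in solution like
semi-flexible polymers: their SAXS form factors follow generalized
Gaussian-coil statistics, and their collective chain motions on the
1–200 ns timescale are visible to NSE as the decay of the normalized
intermediate scattering function I(q,t)/I(q,0). `coildyn` implements the
full analysis chain a combined SAXS/NSE study of an IDP needs, together
with synthetic-data generators so that every stage is testable by
parameter recovery against known ground truth:

- **Form factors** — generalized Gaussian coil
  `P(q) = 1/(ν U^{1/2ν}) γ(1/2ν, U) − 1/(ν U^{1/ν}) γ(1/ν, U)` with
  `U = (2ν+1)(2ν+2) q²R_G²/6`, reducing to the Debye function at ν = ½;
  iterative Guinier analysis with a self-consistent `q_max·R` limit;
  Kratky transforms; the stiff-segment marker `q* = 1.91/l_p`.
- **Structure factors** — `S(q)` from concentration pairs and
  Percus–Yevick hard-sphere fits.
- **Conformer ensembles** — Cα bead chains with prescribed scaling
  exponent ν (exact ideal chains at ν = ½), coordinate (Debye)
  scattering, k-medoids representative selection, CA-only PDB I/O.
- **Hydrodynamics** — Kirkwood double-sum and Rotne–Prager–Yamakawa
  rigid-body diffusion tensors (translational and rotational),
  Stokes–Einstein conversions, the R_H/R_G compactness ratio
  (1.29 globule ↔ 0.67 random coil).
- **Zimm / ZIF fitting** — mode spectrum
  `τ_p = ηR_e³/(√(3π) k_BT) p^{−3ν}`, internal friction as
  `τ_p → τ_p + τ_i`, interaction-corrected diffusion
  `D_t(q) = D_{0,t} H/S(q)`, global multi-q fits of (τ_i, H), and
  model-free stretched-exponential (KWW) analysis.
- **Normal modes** — anisotropic network model (ANM) modes on each
  conformer, multipole dynamic form factors S_l(Q), the rigid-body +
  internal-mode ISF, global fits of (RMSD, τ_NM, H), and the
  Brownian-oscillator friction `ζ = k_BT·τ/RMSD²`.

## Worked example

`examples/04_zif_fit.py` generates a compact-state NSE dataset from the
Zimm-with-internal-friction forward model (τ_i = 70 ns, H = 1.2, 2%
noise) and refits it:

```
chain: Re = 96.3 Å, first Zimm time tau_1 = 78.7 ns
model-free: <beta> = 0.94 (1 = simple exponential, 0.85 = ideal Zimm)
ZIF fit:  tau_i = 70.7 ± 1.6 ns  H = 1.21 ± 0.01  chi2_red = 0.81
Zimm fit (tau_i = 0): chi2_red = 209.6
```

The internal-friction time and the hydrodynamic factor are recovered
within their uncertainties, and the pure Zimm model (all modes relaxing
at their solvent-driven rates) fails by orders of magnitude in reduced
χ² — the quantitative signature of internal friction in compact
disordered chains. The other scripts in `examples/` walk through the
form-factor, structure-factor, ensemble/hydrodynamics and normal-mode
stages, and `examples/06_condition_series.py` runs the whole pipeline
over a five-condition synthetic denaturant series, showing ν rise, τ_i
fall toward its ~40 ns floor, mode RMSD grow and friction ζ drop as the
chain expands.

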