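# Methods

This note documents the models implemented in `coildyn`, the choices made
where the underlying methods leave freedom, and what the synthetic-data
tests do and do not demonstrate.

## Units

Internal units are Å, ns, mPa·s and K. In this system the Boltzmann
constant is `k_B = 13.80649 (mPa·s·Å³)/(ns·K)`, so diffusion constants
come out in Å²/ns and relaxation times in ns with no further conversion.
Momentum transfer is Å⁻¹ everywhere; readers accept nm⁻¹ with an explicit
flag. The Brownian-oscillator force constant and friction are reported in
thermal units (k_BT/Å² and k_BT·ns/Å²).

## Generalized Gaussian coil (`coildyn.sas`)

The form factor of a chain with mean-square internal distances
⟨r²(n,m)⟩ = |n−m|^{2ν} l² is

    P(q) = 1/(ν U^{1/(2ν)}) γ(1/(2ν), U) − 1/(ν U^{1/ν}) γ(1/ν, U),
    U = (2ν+1)(2ν+2) q² R_G²/6,

with γ the lower incomplete gamma function, evaluated as the regularized
function times Γ(a). Below U = 10⁻⁸ the closed form is a 0/0 limit and a
first-order series (P ≈ 1 − q²R_G²/3) keeps P(0) = 1 exact. At ν = ½ the
expression reduces analytically to the Debye function, which the tests
exploit as an oracle. Fits are weighted Levenberg–Marquardt with
parameters (R_G, ν, scale) and an optional constant background (fitted by
default — whether measured curves retain a flat residual background after
buffer subtraction varies by instrument, so the parameter is exposed).
Reported goodness of fit is always the reduced χ² = Σ((I−m)/σ)²/(n−k).

The Guinier analysis iterates the weighted straight-line fit of ln I vs
q², shrinking q_max until q_max·R ≤ limit (1.1 for expanded chains, up to
1.3 for compact states), to a fixed point (|ΔR|/R < 10⁻⁶, ≤ 50
iterations). Degenerate flat curves return R ≈ 0 with a
`below_resolution` flag.

Structure factors are estimated as S(q) = (I_c/c_c)/(I_d/c_d) with the
dilute curve interpolated linearly in ln I; points outside the dilute
support are dropped, never extrapolated, and uncertainties follow
quotient propagation. The Percus–Yevick hard-sphere S(q) is the analytic
closure solution; its three oscillatory kernels suffer catastrophic
cancellation at small qR, so below 2qR_hs = 0.9 they are evaluated from
10th-order Taylor series (coefficients derived symbolically; relative
error < 10⁻¹² at the switch point). Charged-sphere (rescaled MSA) models
are intentionally out of scope; only the uncharged PY branch is
implemented and the model name is reserved in the fitting interface.

## Conformer ensembles (`coildyn.chains`)

The generator replaces pool-generation-plus-selection ensemble modelling:
instead of selecting conformers against measured scattering data, it
produces chains whose statistics are prescribed directly. Steps of fixed
length (3.8 Å Cα spacing; every bond exact) take their *directions* from
fractional Gaussian increments with Hurst index H = ν, giving long-range
step correlations and ⟨R_G(N)⟩ ∝ N^ν. The measured scaling exponent over
N ∈ [50, 300] tracks the target within ±0.03 across ν ∈ [0.4, 0.65]
without calibration; at ν = ½ the construction is exactly a freely
jointed chain (√⟨R_G²⟩ = b√(N/6), ⟨R_e²⟩/⟨R_G²⟩ = 6). This deliberately
matches only global statistics (R_G, ν) — not local dihedral geometry,
persistence length or sequence effects. Consequently ensembles at a given
ν are more compact than a real 169-residue IDP with the same ν (R_G
~14–40 Å rather than 30–60 Å), which is sufficient for the dynamics
stages but means coordinate-level ensembles and analytic form-factor
parameters are specified independently in the synthetic study conditions.

An excluded-volume rejection walk was considered and rejected: it cannot
reach compact targets ν < ½, and its acceptance rate degrades with N,
whereas the correlated-step construction covers the full compact-to-
swollen range deterministically.

Representative selection is 1-d k-medoids on R_G with deterministic
quantile seeding; weights are cluster population fractions. PDB I/O
(CA-only, MODEL/ENDMDL, occupancy = population weight) uses gemmi.

## Hydrodynamics (`coildyn.hydro`)

Two bead-model estimates are provided. The Kirkwood double sum
D = k_BT/(6πηaN) + k_BT/(6πηN²) Σ_{i≠j} 1/r_ij is cheap and carries the
well-known upward pre-averaging bias (≈6% vs. the rigid-body value for
20-bead coils, growing to ~20–25% for 169-bead chains). The rigid-body
estimate builds the 3N×3N Rotne–Prager–Yamakawa mobility supermatrix
(with the overlap branch), inverts to the bead-level resistance,
contracts to the 6×6 rigid-body resistance, moves the reference point to
the center of diffusion and reports D_t = tr(D_tt)/3, D_r = tr(D_rr)/3.
Against a bead-filled sphere it reproduces the Stokes translational value
within 2% and the rotational k_BT/(8πηR³) within 5%. Axially degenerate
geometries (collinear chains, two-bead rigid bodies) have a singular
rotational resistance in a translation-only bead model and are rejected
with a diagnostic.

Default bead radii: 1.9 Å at one residue per bead, 4.5 Å for ~8-residue
beads. Absolute diffusion constants from Cα models are stand-ins (no
hydration shell or side chains); NSE fits therefore take D_0,t as a fixed
external input, exactly as a measured dynamic-light-scattering value is
used, and the bead-model values feed only cross-checks and synthetic
data.

The compactness ratio R_H/R_G classifies chains against the two known
extremes √(5/3) = 1.29 (uniform sphere) and 0.67 (random coil), with
thresholds at the midpoints to 1. The coil extreme is a *long-chain*
limit: the finite-chain Kirkwood ratio of a Gaussian chain is ≈0.73 at
N = 169 and converges as N^{−1/2}. The Monte-Carlo estimator therefore
runs at several chain lengths (100–1200 beads, 9100 chains total) and
extrapolates quadratically in N^{−1/2} with inverse-variance weights
(delta-method errors); validated against the exact Gaussian-chain
expectation, the extrapolated intercept is 0.665 vs. the true 0.664.

## Zimm and ZIF (`coildyn.zimm`)

Mode p of a chain with hydrodynamic interactions relaxes with
τ_p = ηR_e³/(√(3π) k_BT) p^{−3ν}, with R_e = √((2ν+1)(2ν+2)) R_G and
l = R_e/N^ν fixed by the scattering stage. Internal friction adds a
constant: τ_p → τ_p + τ_i. The coherent ISF is the N×N double sum over
B(n,m,t) (static part |n−m|^{2ν}l², mode part 4R_e²/π² Σ_p p^{−(2ν+1)}
cos(πpn/N)cos(πpm/N)(1−e^{−t/τ_p})), evaluated at the experimental
Fourier times and *normalized by its t = 0 value* so the model matches
measured I(q,t)/I(q,0) — the normalization is implicit in the theory and
made explicit here. N = 20 beads by default (≈8 residues per bead);
fits are invariant to doubling N, which the tests assert. A single bead
(N = 1) degenerates to pure center-of-mass diffusion.

Translational diffusion enters as D_t(q) = D_{0,t}·H/S(q) with S(q)
interpolated from the measured structure factor and H a single
q-independent hydrodynamic factor shared across the whole dataset per
condition. The global ZIF fit has (τ_i, H) free, weighted 1/σ², with
points I ≤ 0 excluded; τ_i is fitted as log τ_i to enforce positivity,
and a fit driven to the lower bound is flagged and reported as an upper
limit. The pure-Zimm fit (τ_i ≡ 0) is always evaluated on the same data
for model comparison.

Model-free analysis fits exp(−(Γt)^β) per q with unit amplitude and
reports D_eff = Γ/q² and the unweighted mean ⟨β⟩ over q (the averaging
convention is a package choice). Noise-free Zimm curves for a 20-bead
θ-chain over q = 0.05–0.17 Å⁻¹ with Kirkwood diffusion give ⟨β⟩ ≈ 0.86,
consistent with the ideal-Zimm stretching value 0.85; the mild upward
deviation comes from the diffusion-dominated lowest q and the finite
fitting window.

## Normal modes (`coildyn.nmodes`)

Each conformer gets an ANM: unit springs between bead pairs within the
cutoff, 3N×3N Hessian, six rigid-body null modes removed, the next 10
modes kept with equal weights. The default cutoff is 4× the bond length
(15.2 Å for Cα chains, the conventional Cα-network value): sparser
networks on expanded coils are not infinitesimally rigid and develop
spurious zero-frequency mechanisms, which the code detects (it requires
exactly six numerical null modes) and rejects. The spring constant is
absorbed into the fitted amplitude — only displacement patterns matter.

The single-conformer ISF is

    I(q,t)/I(q,0) = (1 − A + A e^{−t/τ_NM}) e^{−q²D_t t}
                    × Σ_l S_l(q) e^{−l(l+1)D_r t} / Σ_l S_l(q),

with S_l(Q) = 4π Σ_m |Σ_i b_i j_l(Qr_i) Y_lm(Ω_i)|² the multipole terms
(normalized so Σ_l S_l equals the exact orientationally averaged Debye
double sum — the ratio in the ISF is invariant to this choice, which the
tests assert), coordinates re-centered to the scattering-length center
(the rotational term assumes a body-fixed origin), l_max =
⌈Q·r_max⌉ + 10 capped at 60, and D_r per conformer from the rigid-body
RPY tensor. The mode amplitude A(q) = a²ΣF_α/(F + a²ΣF_α) uses mode form
factors F_α(q) orientationally averaged on a deterministic 144-direction
spherical Fibonacci grid (no random sampling, so fits are bitwise
reproducible; doubling the grid changes A by < 10⁻⁴). Ensemble curves
average *full per-conformer ISFs* with population weights (averaging
A(q) and the rotational term separately is ambiguous and was not done).
The common amplitude is reported as per-atom RMSD = a√(n_modes/N),
i.e. the rms of the summed equal-amplitude mode displacement field over
unit-normalized eigenvectors.

The global NM fit has (a → RMSD, τ_NM, H) free with D_{0,t} and S(q)
fixed. The (a, τ_NM) likelihood surface is flat or multimodal when the
mode signal is weak — τ_NM → ∞ exactly mimics a → 0 — so the fit
restarts from a deterministic grid of initial values and keeps the
lowest-χ² solution, and a fitted amplitude consistent with zero trips an
"unidentifiable" flag instead of reporting a meaningless τ_NM.

Identifiability drove the synthetic study conditions: Fisher analysis
shows that per-atom amplitudes of ~2 Å on coil conformers are below the
information content of 2%-noise NSE data (σ_RMSD ≳ 30%), while
amplitudes of 4–6 Å — the physical scale of collective IDP modes — are
recoverable within 15% when the dataset extends to q ≈ 0.3 Å⁻¹ and the
substrate ensemble contains expanded, slowly rotating conformers
(τ_r ≫ τ_NM, separating rotation from mode relaxation). The NM
synthetic fixtures use exactly those conditions.

The Brownian-oscillator conversion ζ = k_BT·τ/RMSD², k = k_BT/RMSD²
links both analyses: a falling ZIF τ_i and a rising NM amplitude at
constant τ_NM both mean loss of internal friction.

## Synthetic data (`coildyn.synthetic`)

All generators are pure functions of (parameters, seed). Noise is
multiplicative Gaussian, σ = noise_frac·I, with a floor of 10⁻³ on
normalized NSE amplitudes; instrument resolution and wavelength smearing
are not modelled. Default grids mirror the instruments: SAS q ∈
0.01–0.7 Å⁻¹ (120 log-spaced points), NSE q ∈ {0.05…0.17} Å⁻¹ with 15
log-spaced Fourier times 0.1–150 ns for polymer-model datasets, and an
extended q ∈ {0.08…0.32} Å⁻¹, 25 times to 200 ns for normal-mode
datasets (short-wavelength settings).

The five-condition series emulates a denaturant titration of a charged
IDP: ν rises 0.48 → 0.53 and form-factor R_G 38 → 55 Å (compact →
swollen), τ_i falls 70 → 40 ns toward a floor, mode RMSD rises
3.5 → 6 Å at constant τ_NM = 7 ns, H and D_{0,t} vary mildly, and the
interparticle interaction is a PY hard sphere. ν values, the τ_i floor
and τ_NM are measured scales; the RMSD and H trajectories are
qualitative by construction. Passing the end-to-end tests shows the
chain of estimators is unbiased and consistent under these idealized
conditions (exact forward models, known noise, matched ensembles); it
does not validate instrument-specific corrections, resolution effects or
the adequacy of the forward models for any particular real protein.

## Numerical notes

- Weighted fits use scipy/lmfit Levenberg–Marquardt; 1σ errors from the
  covariance; reduced χ² with n − k degrees of freedom throughout.
- ISF evaluations reuse precomputed per-conformer tables (S_l, F, ΣF_α,
  D_r), so global NM fits cost O(iterations × q × t) regardless of
  ensemble size.
- Percus–Yevick kernels switch to series below 2qR = 0.9 (see above);
  the generalized-coil form factor switches to series below U = 10⁻⁸.
- All RNG is numpy `default_rng` seeded explicitly; fixture and example
  seeds are recorded in the generated metadata.

## Known limitations

- Ensembles reproduce (R_G, ν) statistics only; no persistence length,
  sequence specificity or side-chain geometry.
- Bead hydrodynamics is not a surface-shell model; absolute D values are
  approximate (hence D_{0,t} is an input to all NSE fits).
- Only the uncharged PY structure factor is implemented; attractive or
  screened-Coulomb interactions are out of scope.
- The Zimm/ZIF implementation covers θ-to-swollen chains (0.3 < ν ≤ 1);
  Rouse dynamics, reptation and temperature-series activation analyses
  are not included.
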