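"""Normal-mode interpretation of NSE spectra on conformer ensembles.

Alternative to the polymer-theory (Zimm/ZIF) picture: each conformer is a
rigid body performing translational and rotational diffusion, decorated
with overdamped internal displacements along the low-frequency normal
modes of an anisotropic network model (ANM).  The single-conformer
intermediate scattering function is

    I(q,t)/I(q,0) = (1 - A(q) + A(q) e^(-t/tau_NM)) * e^(-q^2 D_t t)
                    * sum_l S_l(q) e^(-l(l+1) D_r t) / sum_l S_l(q),

where S_l are the multipole terms of the coherent form factor,

    S_l(Q) = 4 pi sum_m | sum_i b_i j_l(Q r_i) Y_lm(Omega_i) |^2,

and the mode amplitude A(q) = sum_a a^2 F_a(q) / (F(q) + sum_a a^2 F_a(q))
is built from the mode form factors

    F_a(q) = < sum_{k,l} b_k b_l e^{i q (r_k - r_l)} (q·e_k^a)(q·e_l^a) >,

with <.> a deterministic orientational average.  Ensemble curves are the
population-weighted averages of conformer curves.  The global NSE fit has
a common amplitude (reported as per-atom RMSD), a common mode relaxation
time tau_NM and the hydrodynamic factor H free; D_0,t and S(q) are fixed
external inputs.  The overdamped-oscillator relation zeta = k_B T tau/RMSD²
finally converts (RMSD, tau) into an internal friction coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.special import sph_harm_y, spherical_jn

from .chains import BeadChain, Ensemble
from .hydro import DEFAULT_BEAD_RADIUS, rigid_body_diffusion
from .sas import StructureFactorCurve
from .zimm import NSEDataset, effective_diffusion

__all__ = [
    "ANMModes",
    "MultipoleTable",
    "NMModel",
    "NMFitResult",
    "BrownianFriction",
    "anm_modes",
    "multipole_Sl",
    "mode_form_factors",
    "mode_formfactor_amplitude",
    "nm_isf",
    "build_nm_model",
    "fit_nse_nm",
    "brownian_friction",
    "fibonacci_sphere",
]

DEFAULT_N_MODES = 10
DEFAULT_N_DIRECTIONS = 144
LMAX_CAP = 60


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class ANMModes:
    """Nontrivial ANM modes of one conformer.

    ``eigenvectors`` has shape (n_modes, N, 3), unit-normalized; the six
    rigid-body zero modes are excluded.  Eigenvalues are in units of the
    (arbitrary) spring constant, which cancels in all downstream use.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    cutoff: float

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class MultipoleTable:
    """S_l(Q) for l = 0..lmax on a Q grid (one conformer)."""

    Q: np.ndarray
    Sl: np.ndarray       # (lmax + 1, nQ)

    @property
    def lmax(self) -> int:
        return self.Sl.shape[0] - 1

    def total(self) -> np.ndarray:
        """sum_l S_l(Q) — equals the orientationally averaged form factor."""
        return self.Sl.sum(axis=0)


@dataclass
class NMModel:
    """Precomputed per-conformer tables for normal-mode NSE fitting."""

    ensemble: Ensemble
    q: np.ndarray                    # dataset momentum transfers [1/Å]
    Sl: list                         # per chain: (lmax+1, nq) arrays
    F: np.ndarray                    # (n_chain, nq) form factors
    Fsum: np.ndarray                 # (n_chain, nq) sum_a F_a (unit amplitude)
    Dr: np.ndarray                   # (n_chain,) rotational diffusion [1/ns]
    n_modes: int
    n_beads: int
    meta: dict = field(default_factory=dict)

    @property
    def Dr_mean(self) -> float:
        return float(self.ensemble.weights @ self.Dr)

    def amplitude(self, a: float) -> np.ndarray:
        """Population-averaged A(q) for common mode amplitude ``a`` [Å]."""
        A = self.Fsum * a**2 / (self.F + self.Fsum * a**2)
        return self.ensemble.weights @ A


@dataclass
class NMFitResult:
    """Global normal-mode fit of an NSE dataset."""

    RMSD: float                      # per-atom RMS mode displacement [Å]
    RMSD_err: float
    tau_NM: float                    # common mode relaxation time [ns]
    tau_NM_err: float
    H: float
    H_err: float
    chi2_red: float
    amplitude: float                 # raw common amplitude a [Å]
    tau_identifiable: bool           # False when RMSD ~ 0 leaves tau unconstrained
    per_q_chi2: pd.DataFrame


@dataclass
class BrownianFriction:
    """Overdamped-oscillator friction in thermal units.

    k = k_B T/RMSD² is reported as ``k`` [k_B T/Å²] and the friction
    zeta = k tau as ``zeta`` [k_B T·ns/Å²]; multiply by k_B T(T) from
    coildyn._units to convert to mPa·s·Å.
    """

    zeta: float
    k: float
    tau: float      # [ns]
    RMSD: float     # [Å]
    T: float        # [K]


# --------------------------------------------------------------------------- #
# ANM
# --------------------------------------------------------------------------- #

def anm_modes(
    chain: BeadChain,
    cutoff: float | None = None,
    n_modes: int = DEFAULT_N_MODES,
) -> ANMModes:
    """Lowest nontrivial anisotropic-network-model modes of a conformer.

    Builds the 3N x 3N ANM Hessian with unit springs between bead pairs
    within ``cutoff``, removes the six rigid-body null modes and returns
    the next ``n_modes`` eigenpairs.  The default cutoff of 4 x bond
    (15.2 Å for Cα chains, the conventional Cα-network value) is needed
    because sparser networks on expanded coils are not infinitesimally
    rigid and develop spurious zero-frequency mechanisms.
    """
    coords = chain.coords
    n = chain.n_beads
    if cutoff is None:
        cutoff = 4.0 * chain.bond
    if n_modes > 3 * n - 6:
        raise ValueError("n_modes exceeds the number of internal degrees of freedom")

    d = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    contact = (r <= cutoff) & ~np.eye(n, dtype=bool)

    ncomp, _ = connected_components(sparse.csr_matrix(contact), directed=False)
    if ncomp > 1:
        raise ValueError(
            f"contact graph has {ncomp} components at cutoff={cutoff:g} Å; "
            "increase the cutoff"
        )

    H = np.zeros((n, 3, n, 3))
    ii, jj = np.nonzero(contact)
    u = d[ii, jj] / r[ii, jj][:, None]
    blocks = u[:, :, None] * u[:, None, :]
    np.add.at(H, (ii, slice(None), jj, slice(None)), -blocks)
    np.add.at(H, (ii, slice(None), ii, slice(None)), blocks)
    H = H.reshape(3 * n, 3 * n)

    vals, vecs = eigh(H)
    tol = 1e-8 * vals[-1]
    n_zero = int((np.abs(vals) < tol).sum())
    if n_zero != 6:
        raise ValueError(
            f"expected 6 rigid-body modes, found {n_zero}; "
            "degenerate or disconnected geometry"
        )
    sel = slice(6, 6 + n_modes)
    return ANMModes(
        eigenvectors=vecs[:, sel].T.reshape(n_modes, n, 3),
        eigenvalues=vals[sel],
        cutoff=cutoff,
    )


# --------------------------------------------------------------------------- #
# multipole expansion
# --------------------------------------------------------------------------- #

def _lmax_for(Q: np.ndarray, r_max: float, lmax: int | None) -> int:
    if lmax is not None:
        return lmax
    return min(int(np.ceil(np.max(Q) * r_max)) + 10, LMAX_CAP)


def multipole_Sl(chain: BeadChain, Q, lmax: int | None = None) -> MultipoleTable:
    """Multipole terms S_l(Q) of the coherent form factor of one conformer.

    Coordinates are re-centered to the scattering-length center before the
    expansion.  Normalization is such that sum_l S_l(Q) equals the exact
    orientationally averaged double sum (Debye formula); lmax defaults to
    ceil(Q r_max) + 10, capped at 60.
    """
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    b = chain.b
    coords = chain.coords - (b[:, None] * chain.coords).sum(0) / b.sum()
    r = np.linalg.norm(coords, axis=1)
    r_safe = np.where(r > 1e-12, r, 1.0)
    theta = np.arccos(np.clip(np.where(r > 1e-12, coords[:, 2] / r_safe, 1.0), -1, 1))
    phi = np.arctan2(coords[:, 1], coords[:, 0])

    L = _lmax_for(Q, float(r.max()), lmax)
    Sl = np.empty((L + 1, Q.size))
    qr = Q[:, None] * r[None, :]
    for l in range(L + 1):
        jl = spherical_jn(l, qr)                                  # (nQ, N)
        m = np.arange(-l, l + 1)
        Ylm = sph_harm_y(l, m[:, None], theta[None, :], phi[None, :])  # (2l+1, N)
        amp = np.einsum("qi,mi->qm", jl * b[None, :], Ylm.conj())
        Sl[l] = 4 * np.pi * (np.abs(amp) ** 2).sum(axis=1)
    return MultipoleTable(Q=Q, Sl=Sl)


# --------------------------------------------------------------------------- #
# mode form factors and amplitudes
# --------------------------------------------------------------------------- #

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (spherical Fibonacci grid)."""
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    rho = np.sqrt(1 - z**2)
    golden = np.pi * (3 - np.sqrt(5))
    return np.c_[rho * np.cos(golden * i), rho * np.sin(golden * i), z]


def mode_form_factors(
    chain: BeadChain,
    modes: ANMModes,
    Q,
    n_directions: int = DEFAULT_N_DIRECTIONS,
):
    """Orientationally averaged F(q) and per-mode F_a(q) of one conformer.

    Returns (F, Fa) with shapes (nQ,) and (n_modes, nQ).  The average runs
    over a deterministic spherical Fibonacci grid so repeated fits are
    bitwise reproducible.
    """
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    dirs = fibonacci_sphere(n_directions)                  # (nd, 3)
    coords = chain.coords - chain.coords.mean(0)
    b = chain.b
    F = np.empty(Q.size)
    Fa = np.empty((modes.n_modes, Q.size))
    proj_dir = np.einsum("dc,anc->dan", dirs, modes.eigenvectors)  # (nd, nm, N)
    for iq, q in enumerate(Q):
        phase = np.exp(1j * q * dirs @ coords.T)           # (nd, N)
        amp0 = phase @ b                                   # (nd,)
        F[iq] = np.mean(np.abs(amp0) ** 2)
        amp_a = np.einsum("dn,dan->da", phase * b[None, :], q * proj_dir)
        Fa[:, iq] = np.mean(np.abs(amp_a) ** 2, axis=0)
    return F, Fa


def mode_formfactor_amplitude(
    chain: BeadChain,
    modes: ANMModes,
    a: float,
    Q,
    n_directions: int = DEFAULT_N_DIRECTIONS,
) -> np.ndarray:
    """NM amplitude A(q) = a² sum_a F_a / (F + a² sum_a F_a) of one conformer.

    All modes share the common amplitude ``a`` [Å] (equal weighting); A(q)
    is in [0, 1) and vanishes as a -> 0.
    """
    if a < 0:
        raise ValueError("amplitude must be non-negative")
    F, Fa = mode_form_factors(chain, modes, Q, n_directions)
    S = a**2 * Fa.sum(axis=0)
    return S / (F + S)


# --------------------------------------------------------------------------- #
# ISF and fitting
# --------------------------------------------------------------------------- #

def build_nm_model(
    ensemble: Ensemble,
    q,
    eta: float,
    T: float,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    n_modes: int = DEFAULT_N_MODES,
    cutoff: float | None = None,
    lmax: int | None = None,
    n_directions: int = DEFAULT_N_DIRECTIONS,
) -> NMModel:
    """Precompute all conformer tables needed by the NM forward model.

    Rotational diffusion comes from RPY rigid-body hydrodynamics per
    conformer; S_l(Q), F(q) and the unit-amplitude mode form-factor sums
    are tabulated at the dataset momentum transfers.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    Sl, F, Fsum, Dr = [], [], [], []
    for ch in ensemble.chains:
        modes = anm_modes(ch, cutoff=cutoff, n_modes=n_modes)
        tab = multipole_Sl(ch, q, lmax=lmax)
        f, fa = mode_form_factors(ch, modes, q, n_directions)
        Sl.append(tab.Sl)
        F.append(f)
        Fsum.append(fa.sum(axis=0))
        Dr.append(rigid_body_diffusion(ch, eta, T, bead_radius).Dr)
    return NMModel(
        ensemble=ensemble, q=q, Sl=Sl, F=np.array(F), Fsum=np.array(Fsum),
        Dr=np.array(Dr), n_modes=n_modes, n_beads=ensemble.chains[0].n_beads,
        meta={"eta": eta, "T": T, "bead_radius": bead_radius},
    )


def nm_isf(
    model: NMModel,
    q: float,
    t,
    Dt: float,
    a: float,
    tau_NM: float,
) -> np.ndarray:
    """Population-averaged NM intermediate scattering function at one q.

    ``q`` must be one of the momentum transfers the model was built on;
    ``Dt`` is the interaction-corrected translational diffusion [Å²/ns].
    Each conformer uses its own rotational diffusion constant; full
    per-conformer ISFs are averaged with the population weights.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    iq = int(np.argmin(np.abs(model.q - q)))
    if abs(model.q[iq] - q) > 1e-9 * max(q, 1.0):
        raise ValueError(f"q={q} not tabulated in the NM model")
    trans = np.exp(-q * q * Dt * t)
    out = np.zeros_like(t)
    for w, Sl, F, Fsum, Dr in zip(
        model.ensemble.weights, model.Sl, model.F, model.Fsum, model.Dr
    ):
        S = Sl[:, iq]
        ls = np.arange(S.size)
        rot = (S[:, None] * np.exp(-ls[:, None] * (ls[:, None] + 1) * Dr * t[None, :])
               ).sum(0) / S.sum()
        A = a**2 * Fsum[iq] / (F[iq] + a**2 * Fsum[iq])
        out += w * (1 - A + A * np.exp(-t / tau_NM)) * rot
    return trans * out


def fit_nse_nm(
    ds: NSEDataset,
    model: NMModel,
    D0t: float,
    Sq: StructureFactorCurve | None = None,
    a_inits=(1.0, 3.0, 10.0, 25.0),
    tau_inits=(3.0, 10.0, 30.0),
) -> NMFitResult:
    """Global weighted NM fit of an NSE dataset.

    Free parameters: common mode amplitude a (reported as per-atom
    RMSD = a sqrt(n_modes/N)), common relaxation time tau_NM and the
    hydrodynamic factor H.  D_0,t and S(q) are fixed inputs.  The (a,
    tau_NM) likelihood surface can be multimodal when the mode amplitude
    is weak, so the Levenberg-Marquardt fit is restarted from a small
    deterministic grid of initial values and the lowest-chi² solution
    kept.
    """
    groups = [(q, t, I, sig) for q, t, I, sig in ds.groups()]
    pos = [(I > 0) for _, _, I, _ in groups]
    npts = sum(int(m.sum()) for m in pos)

    def residuals(x):
        a, tau, H = x["a"].value, x["tau_NM"].value, x["H"].value
        out = []
        for (q, t, I, sig), m in zip(groups, pos):
            Dt = effective_diffusion(D0t, H, Sq, q)[0]
            modelI = nm_isf(model, q, t[m], Dt, a, tau)
            out.append((I[m] - modelI) / sig[m])
        return np.concatenate(out)

    mini = None
    for a0 in a_inits:
        for tau0 in tau_inits:
            pars = lmfit.Parameters()
            pars.add("a", value=a0, min=0.0, max=100.0)
            pars.add("tau_NM", value=tau0, min=1e-3, max=1e4)
            pars.add("H", value=1.0, min=1e-3, max=100.0)
            trial = lmfit.minimize(residuals, pars, method="leastsq")
            if trial.success and (mini is None or trial.chisqr < mini.chisqr):
                mini = trial
    if mini is None:
        raise RuntimeError("NM global fit did not converge from any start")

    scale = np.sqrt(model.n_modes / model.n_beads)
    a = mini.params["a"].value
    a_err = mini.params["a"].stderr or np.nan
    tau = mini.params["tau_NM"].value
    tau_err = mini.params["tau_NM"].stderr or np.nan
    H = mini.params["H"].value
    H_err = mini.params["H"].stderr or np.nan

    identifiable = a * scale > 3 * (a_err * scale if np.isfinite(a_err) else 0) and a > 1e-3
    if not identifiable:
        warnings.warn(
            "fitted mode amplitude is consistent with zero; "
            "tau_NM is not identifiable on these data"
        )

    rows = []
    for (q, t, I, sig), m in zip(groups, pos):
        Dt = effective_diffusion(D0t, H, Sq, q)[0]
        modelI = nm_isf(model, q, t[m], Dt, a, tau)
        rows.append({"q": q, "n": int(m.sum()),
                     "chi2_red": float((((I[m] - modelI) / sig[m]) ** 2).mean())})

    return NMFitResult(
        RMSD=float(a * scale), RMSD_err=float(a_err * scale),
        tau_NM=float(tau), tau_NM_err=float(tau_err),
        H=float(H), H_err=float(H_err),
        chi2_red=float(mini.chisqr / max(npts - 3, 1)),
        amplitude=float(a), tau_identifiable=bool(identifiable),
        per_q_chi2=pd.DataFrame(rows),
    )


def brownian_friction(RMSD: float, tau: float, T: float) -> BrownianFriction:
    """Overdamped Brownian-oscillator friction from (RMSD, tau).

    The oscillator with force constant k and friction zeta has
    RMSD² = k_B T/k and tau = zeta/k, hence zeta = k_B T tau/RMSD².
    Reported in thermal units: k in k_B T/Å², zeta in k_B T·ns/Å².
    """
    if RMSD <= 0 or tau <= 0 or T <= 0:
        raise ValueError("RMSD, tau and T must be positive")
    k = 1.0 / RMSD**2
    return BrownianFriction(zeta=k * tau, k=k, tau=tau, RMSD=RMSD, T=T)
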