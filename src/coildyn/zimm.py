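"""Zimm and Zimm-with-internal-friction (ZIF) analysis of NSE spectra.

The Zimm model treats the disordered chain as N beads connected by entropic
springs with hydrodynamic interactions.  Mode p relaxes with

    tau_p = eta R_e^3 / (sqrt(3 pi) k_B T) * p^(-3 nu),

and internal friction adds a constant shift tau_p -> tau_p + tau_i (ZIF).
The coherent intermediate scattering function is the double sum

    I(q,t) = exp(-q^2 D_t t)/N * sum_{n,m} exp(-q^2 B(n,m,t)/6),
    B(n,m,t) = |n-m|^(2 nu) l^2
             + (4 R_e^2/pi^2) sum_p p^-(2 nu + 1)
               cos(pi p n/N) cos(pi p m/N) (1 - exp(-t/tau_p)),

normalized by its t = 0 value so that the model matches the measured
I(q,t)/I(q,0).  Translational diffusion is corrected for hydrodynamic and
interparticle interactions via D_t(q) = D_0,t * H / S(q).

Chain-structure inputs (R_G, nu) come from small-angle scattering, D_0,t
from dynamic light scattering and S(q) from a concentration series; the
global NSE fit then has only the internal-friction time tau_i and the
hydrodynamic factor H free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import optimize

from ._units import kBT
from .sas import StructureFactorCurve

__all__ = [
    "NSEDataset",
    "ZimmParams",
    "ZIFFitResult",
    "StretchedExpResult",
    "zimm_mode_times",
    "zimm_isf",
    "zif_isf",
    "effective_diffusion",
    "fit_stretched_exponential",
    "fit_nse_zif",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class NSEDataset:
    """Normalized spin-echo relaxation data grouped by momentum transfer.

    ``data`` is a DataFrame with columns (q [1/Å], t [ns], I, sigma) where
    I is the normalized intermediate scattering function I(q,t)/I(q,0).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"q", "t", "I", "sigma"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"NSE data needs columns {sorted(required)}")
        if (self.data["t"] < 0).any():
            raise ValueError("negative Fourier times")
        if self.data.duplicated(subset=["q", "t"]).any():
            raise ValueError("duplicate (q, t) points")

    @classmethod
    def from_arrays(cls, q, t, I, sigma, meta: dict | None = None) -> "NSEDataset":
        df = pd.DataFrame({"q": np.asarray(q, float), "t": np.asarray(t, float),
                           "I": np.asarray(I, float), "sigma": np.asarray(sigma, float)})
        return cls(df.sort_values(["q", "t"], ignore_index=True), meta or {})

    @property
    def q_values(self) -> np.ndarray:
        return np.unique(self.data["q"].to_numpy())

    def groups(self):
        """Iterate (q, t-array, I-array, sigma-array) per momentum transfer."""
        for q, g in self.data.groupby("q", sort=True):
            yield float(q), g["t"].to_numpy(), g["I"].to_numpy(), g["sigma"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ZimmParams:
    """Polymer-theory state of a Zimm/ZIF chain.

    R_G and nu come from scattering; the derived end-to-end distance is
    R_e = sqrt((2 nu + 1)(2 nu + 2)) R_G and the bond length l = R_e/N^nu.
    tau_i = 0 gives the pure Zimm model.
    """

    RG: float               # [Å]
    nu: float
    eta: float              # solvent viscosity [mPa·s]
    T: float                # [K]
    N: int = 20             # bead count; also the mode cutoff p_max
    tau_i: float = 0.0      # internal-friction time [ns]

    def __post_init__(self):
        if self.RG <= 0 or self.eta <= 0 or self.T <= 0:
            raise ValueError("RG, eta and T must be positive")
        if not (0.3 <= self.nu <= 1.0):
            raise ValueError("nu outside (0.3, 1.0)")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tau_i < 0:
            raise ValueError("tau_i must be non-negative")

    @property
    def Re(self) -> float:
        """End-to-end distance [Å]."""
        return float(np.sqrt((2 * self.nu + 1) * (2 * self.nu + 2)) * self.RG)

    @property
    def bond_length(self) -> float:
        """Effective bead separation l = R_e/N^nu [Å]."""
        return self.Re / self.N**self.nu

    @property
    def tau_zimm(self) -> float:
        """Longest Zimm time eta R_e^3/(sqrt(3 pi) k_B T) [ns] (p = 1, tau_i = 0)."""
        return self.eta * self.Re**3 / (np.sqrt(3 * np.pi) * kBT(self.T))


@dataclass
class ZIFFitResult:
    """Global ZIF fit of an NSE dataset."""

    tau_i: float
    tau_i_err: float
    H: float
    H_err: float
    chi2_red: float
    chi2_red_zimm: float          # same fit with tau_i frozen at 0
    H_zimm: float
    tau_i_at_bound: bool          # tau_i ran into its lower bound
    per_q_chi2: pd.DataFrame
    params: ZimmParams


@dataclass
class StretchedExpResult:
    """Model-free KWW analysis exp(-(Gamma t)^beta) per momentum transfer."""

    table: pd.DataFrame           # columns q, Deff, Deff_err, beta, beta_err
    beta_mean: float              # unweighted mean of beta over q


# --------------------------------------------------------------------------- #
# forward models
# --------------------------------------------------------------------------- #

def zimm_mode_times(params: ZimmParams) -> np.ndarray:
    """Mode relaxation times tau_p (+ tau_i if set) for p = 1..N [ns]."""
    p = np.arange(1, params.N + 1)
    return params.tau_zimm * p ** (-3.0 * params.nu) + params.tau_i


def _zimm_B(params: ZimmParams, t: np.ndarray):
    """Internal mean-square displacement kernel B(n,m,t) [Å²], plus B(n,m,0)."""
    N, nu = params.N, params.nu
    l, Re = params.bond_length, params.Re
    tau_p = zimm_mode_times(params)
    p = np.arange(1, N + 1)
    n = np.arange(1, N + 1)
    static = np.abs(n[:, None] - n[None, :]) ** (2 * nu) * l**2
    cos_pn = np.cos(np.pi * np.outer(p, n) / N)                     # (p, n)
    amp = 4 * Re**2 / np.pi**2 * p ** -(2 * nu + 1.0)
    mode_nm = np.einsum("p,pn,pm->pnm", amp, cos_pn, cos_pn)
    decay = 1.0 - np.exp(-t[:, None] / tau_p[None, :])              # (t, p)
    return static[None] + np.einsum("tp,pnm->tnm", decay, mode_nm), static


def zimm_isf(params: ZimmParams, q: float, t, Dt: float = 0.0) -> np.ndarray:
    """Normalized Zimm intermediate scattering function I(q,t)/I(q,0).

    ``Dt`` is the (possibly S(q)/H-corrected) translational diffusion in
    Å²/ns.  The internal double sum is evaluated relative to its t = 0
    value, so the result is exactly 1 at t = 0.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if q <= 0:
        raise ValueError("q must be positive")
    if params.N == 1:
        # a single bead has no internal modes: pure center-of-mass diffusion
        return np.exp(-q * q * Dt * t)
    B, B0 = _zimm_B(params, t)
    S = np.exp(-(q * q / 6.0) * B).sum(axis=(1, 2))
    S0 = np.exp(-(q * q / 6.0) * B0).sum()
    return np.exp(-q * q * Dt * t) * S / S0


def zif_isf(params: ZimmParams, q: float, t, Dt: float = 0.0,
            tau_i: float | None = None) -> np.ndarray:
    """ZIF intermediate scattering function: Zimm with tau_p -> tau_p + tau_i.

    With tau_i = 0 this is identical to :func:`zimm_isf`.  ``tau_i``
    overrides the value carried by ``params`` when given.
    """
    if tau_i is not None:
        params = ZimmParams(RG=params.RG, nu=params.nu, eta=params.eta,
                            T=params.T, N=params.N, tau_i=tau_i)
    return zimm_isf(params, q, t, Dt)


def effective_diffusion(
    D0t: float, H: float, Sq: StructureFactorCurve | None, q
) -> np.ndarray:
    """Interaction-corrected diffusion D_t(q) = D_0,t * H / S(q).

    ``Sq = None`` means no interparticle correction (S = 1).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    S = np.ones_like(q) if Sq is None else Sq(q)
    return D0t * H / S


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #

def fit_stretched_exponential(ds: NSEDataset, min_points: int = 5) -> StretchedExpResult:
    """Per-q KWW fits exp(-(Gamma t)^beta) with amplitude fixed to 1.

    Reports the effective diffusion D_eff = Gamma/q² [Å²/ns] and the
    stretching exponent beta per q, and the unweighted mean <beta>.
    q-groups with fewer than ``min_points`` usable times are skipped with a
    warning.
    """
    rows = []
    for q, t, I, sig in ds.groups():
        ok = (t > 0) & (I > 0)
        if ok.sum() < min_points:
            warnings.warn(f"q={q:g}: fewer than {min_points} usable points, skipped")
            continue

        def kww(tv, gamma, beta):
            return np.exp(-np.clip((gamma * tv) ** beta, 0, 700))

        decay = -np.log(np.clip(I[ok][-1], 1e-6, 1.0 - 1e-9))
        p0 = [max(decay ** (1 / 0.9) / t[ok][-1], 1e-6), 0.9]
        popt, pcov = optimize.curve_fit(
            kww, t[ok], I[ok], p0=p0, sigma=sig[ok], absolute_sigma=True,
            bounds=([1e-8, 0.05], [np.inf, 1.0]), maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        rows.append({"q": q, "Deff": popt[0] / q**2, "Deff_err": perr[0] / q**2,
                     "beta": popt[1], "beta_err": perr[1]})
    if not rows:
        raise ValueError("no q-group had enough points for a KWW fit")
    table = pd.DataFrame(rows)
    return StretchedExpResult(table=table, beta_mean=float(table["beta"].mean()))


def fit_nse_zif(
    ds: NSEDataset,
    params: ZimmParams,
    D0t: float,
    Sq: StructureFactorCurve | None = None,
    tau_i_init: float = 30.0,
    tau_i_bounds: tuple = (1e-3, 1e4),
) -> ZIFFitResult:
    """Global weighted ZIF fit across all (q, t) of an NSE dataset.

    Chain structure (R_G, nu), solvent (eta, T) and D_0,t are fixed inputs;
    free parameters are the q-independent hydrodynamic factor H and the
    internal-friction time tau_i (fitted as log tau_i to enforce
    positivity).  The pure-Zimm fit (tau_i frozen at 0) is evaluated on the
    same data for model comparison.
    """
    groups = [(q, t, I, sig) for q, t, I, sig in ds.groups()]
    pos = [(I > 0) for _, _, I, _ in groups]
    npts = sum(int(m.sum()) for m in pos)

    def residuals(x, with_tau):
        H = x["H"].value
        tau_i = np.exp(x["log_tau_i"].value) if with_tau else 0.0
        out = []
        for (q, t, I, sig), m in zip(groups, pos):
            Dt = effective_diffusion(D0t, H, Sq, q)[0]
            model = zif_isf(params, q, t[m], Dt, tau_i=tau_i)
            out.append((I[m] - model) / sig[m])
        return np.concatenate(out)

    def run(with_tau):
        pars = lmfit.Parameters()
        pars.add("H", value=1.0, min=1e-3, max=100.0)
        pars.add("log_tau_i", value=np.log(tau_i_init),
                 min=np.log(tau_i_bounds[0]), max=np.log(tau_i_bounds[1]),
                 vary=with_tau)
        mini = lmfit.minimize(residuals, pars, kws={"with_tau": with_tau},
                              method="leastsq")
        if not mini.success:
            raise RuntimeError(f"ZIF global fit did not converge: {mini.message}")
        return mini

    res = run(True)
    res0 = run(False)

    nvar = 2
    chi2_red = res.chisqr / max(npts - nvar, 1)
    chi2_red_zimm = res0.chisqr / max(npts - 1, 1)

    H = res.params["H"].value
    H_err = res.params["H"].stderr or np.nan
    log_tau = res.params["log_tau_i"]
    tau_i = float(np.exp(log_tau.value))
    tau_i_err = tau_i * (log_tau.stderr if log_tau.stderr else np.nan)
    at_bound = bool(log_tau.value <= np.log(tau_i_bounds[0]) + 1e-6)
    if at_bound:
        warnings.warn(
            f"tau_i hit its lower bound ({tau_i_bounds[0]} ns); "
            "report as an upper limit / consistent with pure Zimm"
        )

    rows = []
    for (q, t, I, sig), m in zip(groups, pos):
        Dt = effective_diffusion(D0t, H, Sq, q)[0]
        model = zif_isf(params, q, t[m], Dt, tau_i=tau_i)
        rows.append({"q": q, "n": int(m.sum()),
                     "chi2_red": float((((I[m] - model) / sig[m]) ** 2).mean())})

    fitted = ZimmParams(RG=params.RG, nu=params.nu, eta=params.eta,
                        T=params.T, N=params.N, tau_i=tau_i)
    return ZIFFitResult(
        tau_i=tau_i, tau_i_err=float(tau_i_err), H=float(H), H_err=float(H_err),
        chi2_red=float(chi2_red), chi2_red_zimm=float(chi2_red_zimm),
        H_zimm=float(res0.params["H"].value), tau_i_at_bound=at_bound,
        per_q_chi2=pd.DataFrame(rows), params=fitted,
    )
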