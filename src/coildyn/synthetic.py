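"""Synthetic-data generators with recorded ground truth.

Every stage of the analysis chain can be exercised without measured data:
noisy small-angle curves from the generalized Gaussian-coil model, NSE
relaxation datasets from the Zimm/ZIF and normal-mode forward models,
Percus-Yevick structure factors, and a five-condition denaturant series
emulating the compact-to-expanded transition of a disordered protein.
Each generator is a pure function of (parameters, seed) and returns the
generating :class:`GroundTruth` alongside the dataset.

Noise model: multiplicative Gaussian, sigma = noise_frac * I, with an
absolute floor of 1e-3 on normalized NSE amplitudes.  Instrumental
resolution and wavelength smearing are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .chains import Ensemble, generate_ensemble
from .nmodes import NMModel, build_nm_model, nm_isf
from .sas import (
    GaussCoilParams,
    HardSphereParams,
    ScatteringCurve,
    StructureFactorCurve,
    gauss_coil_formfactor,
    hard_sphere_sq,
)
from .zimm import NSEDataset, ZimmParams, effective_diffusion, zif_isf

__all__ = [
    "GroundTruth",
    "ConditionBundle",
    "DEFAULT_SAXS_Q",
    "DEFAULT_NSE_Q",
    "DEFAULT_NSE_NM_Q",
    "DEFAULT_NSE_T",
    "make_saxs",
    "make_structure_factor",
    "make_nse_zif",
    "make_nse_nm",
    "make_condition_series",
]

#: small-angle q grid [1/Å], logarithmic over the instrument range
DEFAULT_SAXS_Q = np.geomspace(0.01, 0.7, 120)
#: spin-echo momentum transfers [1/Å] for polymer-model datasets
DEFAULT_NSE_Q = np.array([0.05, 0.08, 0.11, 0.14, 0.17])
#: extended q set [1/Å] for normal-mode datasets (short-wavelength settings)
DEFAULT_NSE_NM_Q = np.array([0.08, 0.11, 0.14, 0.17, 0.20, 0.24, 0.28, 0.32])
#: Fourier times [ns]
DEFAULT_NSE_T = np.logspace(np.log10(0.1), np.log10(150), 15)

NSE_SIGMA_FLOOR = 1e-3


@dataclass
class GroundTruth:
    """Generating model and parameters of a synthetic dataset."""

    model: str
    params: dict
    seed: int | None
    noise_frac: float

    def as_dict(self) -> dict:
        return asdict(self)


def _noisy(I: np.ndarray, noise_frac: float, rng, floor: float = 0.0):
    sigma = np.maximum(noise_frac * np.abs(I), floor)
    if noise_frac == 0 and floor == 0:
        return I.copy(), np.full_like(I, 1e-12)
    if noise_frac == 0:
        return I.copy(), sigma
    return I + rng.standard_normal(I.shape) * sigma, sigma


# --------------------------------------------------------------------------- #
# SAS
# --------------------------------------------------------------------------- #

def make_saxs(
    params: GaussCoilParams,
    q: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int | None = None,
) -> tuple[ScatteringCurve, GroundTruth]:
    """Noisy generalized-Gaussian-coil curve; sigma = noise_frac * I."""
    q = DEFAULT_SAXS_Q if q is None else np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    I0 = gauss_coil_formfactor(params, q)
    I, sigma = _noisy(I0, noise_frac, rng)
    truth = GroundTruth("gauss_coil", {"RG": params.RG, "nu": params.nu,
                                       "scale": params.scale,
                                       "background": params.background},
                        seed, noise_frac)
    curve = ScatteringCurve(q, I, sigma, meta={"synthetic": True, **truth.as_dict()})
    return curve, truth


def make_structure_factor(
    params: HardSphereParams,
    q: np.ndarray | None = None,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> tuple[StructureFactorCurve, GroundTruth]:
    """Percus-Yevick hard-sphere S(q), optionally with multiplicative noise."""
    q = DEFAULT_SAXS_Q if q is None else np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    S0 = hard_sphere_sq(params, q)
    S, sigma = _noisy(S0, noise_frac, rng)
    truth = GroundTruth("py_hard_sphere", {"R_hs": params.R_hs, "phi": params.phi},
                        seed, noise_frac)
    return StructureFactorCurve(q, S, sigma, meta=truth.as_dict()), truth


# --------------------------------------------------------------------------- #
# NSE
# --------------------------------------------------------------------------- #

def make_nse_zif(
    params: ZimmParams,
    D0t: float,
    H: float = 1.0,
    Sq: StructureFactorCurve | None = None,
    q: np.ndarray | None = None,
    t: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int | None = None,
) -> tuple[NSEDataset, GroundTruth]:
    """NSE dataset from the Zimm/ZIF forward model (tau_i taken from params)."""
    q = DEFAULT_NSE_Q if q is None else np.asarray(q, dtype=float)
    t = DEFAULT_NSE_T if t is None else np.asarray(t, dtype=float)
    rng = np.random.default_rng(seed)
    rows_q, rows_t, rows_I, rows_s = [], [], [], []
    for qi in q:
        Dt = effective_diffusion(D0t, H, Sq, qi)[0]
        y = zif_isf(params, qi, t, Dt)
        I, sigma = _noisy(y, noise_frac, rng, floor=NSE_SIGMA_FLOOR)
        rows_q += [qi] * t.size
        rows_t += list(t)
        rows_I += list(I)
        rows_s += list(sigma)
    truth = GroundTruth(
        "zif" if params.tau_i > 0 else "zimm",
        {"RG": params.RG, "nu": params.nu, "eta": params.eta, "T": params.T,
         "N": params.N, "tau_i": params.tau_i, "H": H, "D0t": D0t},
        seed, noise_frac)
    ds = NSEDataset.from_arrays(rows_q, rows_t, rows_I, rows_s,
                                meta={"T": params.T, "eta": params.eta,
                                      **truth.as_dict()})
    return ds, truth


def make_nse_nm(
    model: NMModel,
    D0t: float,
    RMSD: float,
    tau_NM: float,
    H: float = 1.0,
    Sq: StructureFactorCurve | None = None,
    t: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int | None = None,
) -> tuple[NSEDataset, GroundTruth]:
    """NSE dataset from the normal-mode forward model on a conformer ensemble.

    The q set is the one the NM model was tabulated on; the common mode
    amplitude is specified as the per-atom RMSD [Å].
    """
    t = DEFAULT_NSE_T if t is None else np.asarray(t, dtype=float)
    rng = np.random.default_rng(seed)
    a = RMSD / np.sqrt(model.n_modes / model.n_beads)
    rows_q, rows_t, rows_I, rows_s = [], [], [], []
    for qi in model.q:
        Dt = effective_diffusion(D0t, H, Sq, qi)[0]
        y = nm_isf(model, qi, t, Dt, a, tau_NM)
        I, sigma = _noisy(y, noise_frac, rng, floor=NSE_SIGMA_FLOOR)
        rows_q += [qi] * t.size
        rows_t += list(t)
        rows_I += list(I)
        rows_s += list(sigma)
    truth = GroundTruth(
        "normal_modes",
        {"RMSD": RMSD, "tau_NM": tau_NM, "H": H, "D0t": D0t,
         "Dr_mean": model.Dr_mean, "n_modes": model.n_modes},
        seed, noise_frac)
    ds = NSEDataset.from_arrays(rows_q, rows_t, rows_I, rows_s,
                                meta=truth.as_dict())
    return ds, truth


# --------------------------------------------------------------------------- #
# condition series
# --------------------------------------------------------------------------- #

@dataclass
class ConditionBundle:
    """All synthetic data of one denaturant condition."""

    label: str
    truth: dict
    saxs: ScatteringCurve
    sq: StructureFactorCurve
    nse_zif: NSEDataset
    nse_nm: NSEDataset
    ensemble: Ensemble
    nm_model: NMModel
    meta: dict = field(default_factory=dict)


# The emulated compact -> expanded arc.  nu follows the measured trend of a
# charged disordered protein titrated with denaturant (0.48/0.49 compact,
# ~0.53 swollen); tau_i relaxes from ~70 ns toward a 40 ns floor; mode RMSD
# grows with expansion; form-factor R_G values span the measured 30-60 Å
# window (the bead ensembles, built at fixed Cα spacing without local
# stiffness, are correspondingly more compact).
CONDITION_TABLE = [
    #  label      RG_sas  nu    tau_i  RMSD  tau_NM  H     D0t   phi
    ("0.0 M",     40.0,  0.48,  70.0,  3.5,   7.0,  1.00,  4.4, 0.06),
    ("0.2 M",     38.0,  0.49,  68.0,  3.8,   7.0,  1.05,  4.6, 0.06),
    ("1.0 M",     45.0,  0.53,  55.0,  4.5,   7.0,  1.20,  3.9, 0.05),
    ("4.0 M",     52.0,  0.53,  45.0,  5.3,   7.0,  1.20,  3.4, 0.05),
    ("6.0 M",     55.0,  0.53,  40.0,  6.0,   7.0,  1.20,  3.2, 0.05),
]

_SERIES_ETA = 1.1   # nominal solvent viscosity [mPa·s]
_SERIES_T = 295.0   # sample temperature [K]


def make_condition_series(
    seed: int = 0,
    noise_frac: float = 0.02,
    n_chains: int = 40,
    n_res: int = 169,
) -> list[ConditionBundle]:
    """Five-condition synthetic denaturant series (compact -> expanded).

    Per condition: a noisy small-angle curve, a PY structure factor, a
    conformer ensemble with the condition's scaling exponent, and NSE
    datasets from both the ZIF and the normal-mode forward models with the
    ground-truth parameters of :data:`CONDITION_TABLE`.  nu and RMSD are
    monotone along the series by construction, tau_i monotonically
    approaches its floor.
    """
    rng = np.random.default_rng(seed)
    bundles = []
    for label, RG, nu, tau_i, RMSD, tau_NM, H, D0t, phi in CONDITION_TABLE:
        s_sax, s_ens, s_zif, s_nm = rng.integers(0, 2**31 - 1, size=4)
        saxs, t_sax = make_saxs(GaussCoilParams(RG=RG, nu=nu),
                                noise_frac=noise_frac, seed=int(s_sax))
        sq, _ = make_structure_factor(HardSphereParams(R_hs=1.3 * RG, phi=phi))

        ens = generate_ensemble(n_chains, n_res, nu, seed=int(s_ens))
        # NM substrate: the most expanded, slowly rotating conformers carry
        # the detectable mode signal; pick the upper R_G quartile
        rgs = ens.rgs()
        top = np.argsort(rgs)[-max(4, n_chains // 8):]
        nm_ens = Ensemble([ens.chains[i] for i in top])
        nm_model = build_nm_model(nm_ens, DEFAULT_NSE_NM_Q,
                                  eta=_SERIES_ETA, T=_SERIES_T)

        zp = ZimmParams(RG=RG, nu=nu, eta=_SERIES_ETA, T=_SERIES_T, tau_i=tau_i)
        nse_zif, t_zif = make_nse_zif(zp, D0t=D0t, H=H, Sq=sq,
                                      noise_frac=noise_frac, seed=int(s_zif))
        t_nm_grid = np.logspace(np.log10(0.1), np.log10(200), 25)
        nse_nm, t_nm = make_nse_nm(nm_model, D0t=D0t, RMSD=RMSD, tau_NM=tau_NM,
                                   H=H, Sq=sq, t=t_nm_grid,
                                   noise_frac=noise_frac, seed=int(s_nm))
        truth = {"label": label, "RG": RG, "nu": nu, "tau_i": tau_i,
                 "RMSD": RMSD, "tau_NM": tau_NM, "H": H, "D0t": D0t,
                 "phi": phi, "eta": _SERIES_ETA, "T": _SERIES_T,
                 "seed": seed, "noise_frac": noise_frac}
        bundles.append(ConditionBundle(
            label=label, truth=truth, saxs=saxs, sq=sq,
            nse_zif=nse_zif, nse_nm=nse_nm, ensemble=ens, nm_model=nm_model,
            meta={"subseeds": [int(s_sax), int(s_ens), int(s_zif), int(s_nm)]},
        ))
    return bundles
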