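"""Small-angle scattering profiles of disordered chains.

Form-factor models (generalized Gaussian coil), Guinier analysis, Kratky
transform, concentration-series structure-factor estimation and
Percus-Yevick hard-sphere fitting.  This is the structural stage of the
analysis: it supplies the radius of gyration R_G, the scaling exponent nu
and the interparticle structure factor S(q) that the neutron spin-echo
fitting stages take as fixed inputs.

The generalized Gaussian coil describes a polymer with mean-square
inter-residue distances growing as |n-m|^(2*nu):

    P(q) = 1/(nu*U^(1/(2 nu))) * gamma_inc(1/(2 nu), U)
         - 1/(nu*U^(1/nu))     * gamma_inc(1/nu, U),
    U    = (2 nu + 1)(2 nu + 2) q^2 R_G^2 / 6,

with gamma_inc the lower incomplete gamma function.  At nu = 1/2 it reduces
to the classical Debye function of a Gaussian chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "ScatteringCurve",
    "GaussCoilParams",
    "GaussCoilFit",
    "GuinierResult",
    "StructureFactorCurve",
    "HardSphereParams",
    "HardSphereFit",
    "gauss_coil_formfactor",
    "fit_gauss_coil",
    "guinier_fit",
    "kratky_transform",
    "estimate_structure_factor",
    "hard_sphere_sq",
    "fit_hard_sphere",
    "stiff_segment_q",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class ScatteringCurve:
    """A (q, I, sigma) scattering profile.

    q is the momentum transfer in 1/Å (strictly increasing), I the intensity
    in arbitrary units and sigma its 1-sigma uncertainty.  ``meta`` carries
    free-form labels such as the protein concentration in % w/v
    (``concentration``), the probe (``SAXS``/``SANS``) or a condition label.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I and sigma must have the same length")
        if self.q.ndim != 1:
            raise ValueError("expected 1-d arrays")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    def __len__(self) -> int:
        return self.q.size

    def crop(self, qmin: float | None = None, qmax: float | None = None) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax."""
        m = np.ones_like(self.q, dtype=bool)
        if qmin is not None:
            m &= self.q >= qmin
        if qmax is not None:
            m &= self.q <= qmax
        return ScatteringCurve(self.q[m], self.I[m], self.sigma[m], dict(self.meta))


@dataclass
class GaussCoilParams:
    """Parameters of the generalized Gaussian-coil form factor."""

    RG: float                  # radius of gyration [Å]
    nu: float                  # scaling exponent
    scale: float = 1.0         # forward intensity I(0)
    background: float = 0.0    # constant additive term

    def __post_init__(self):
        if self.RG <= 0:
            raise ValueError("RG must be positive")
        if not (0.3 <= self.nu <= 1.0):
            raise ValueError(f"nu={self.nu} outside the supported range [0.3, 1.0]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class GaussCoilFit:
    """Result of a weighted generalized-Gaussian-coil fit."""

    params: GaussCoilParams
    stderr: GaussCoilParams          # 1-sigma errors in the same fields
    covariance: np.ndarray
    chi2_red: float
    n_points: int


@dataclass
class GuinierResult:
    """Result of an iterative Guinier fit ln I ~ ln I0 - R² q²/3."""

    RGuinier: float       # [Å]
    I0: float
    qmax_used: float      # [1/Å]
    qmaxR: float          # q_max * R_Guinier actually achieved
    n_points: int
    below_resolution: bool = False

    def __post_init__(self):
        if self.RGuinier < 0:
            raise ValueError("RGuinier must be non-negative")


@dataclass
class StructureFactorCurve:
    """Interparticle structure factor S(q) with propagated uncertainties."""

    q: np.ndarray
    S: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    def __call__(self, q) -> np.ndarray:
        """Interpolate S onto ``q`` (linear, clipped to the measured support)."""
        return np.interp(np.asarray(q, dtype=float), self.q, self.S)


@dataclass
class HardSphereParams:
    """Effective hard-sphere radius [Å] and volume fraction."""

    R_hs: float
    phi: float

    def __post_init__(self):
        if self.R_hs <= 0:
            raise ValueError("R_hs must be positive")
        if not (0.0 <= self.phi < 0.74):
            raise ValueError("phi must be in [0, 0.74)")


@dataclass
class HardSphereFit:
    params: HardSphereParams
    stderr: HardSphereParams
    chi2_red: float


# --------------------------------------------------------------------------- #
# generalized Gaussian coil
# --------------------------------------------------------------------------- #

def _lower_gamma(a: float, x: np.ndarray) -> np.ndarray:
    """Lower incomplete gamma function gamma(a, x) (unregularized)."""
    return special.gammainc(a, x) * special.gamma(a)


def gauss_coil_formfactor(params: GaussCoilParams, q) -> np.ndarray:
    """Generalized Gaussian-coil intensity scale*P(q) + background.

    P(0) = 1 exactly; a first-order series in U is used below U = 1e-8 where
    the closed form is numerically indeterminate (0/0).
    """
    q = np.asarray(q, dtype=float)
    nu, RG = params.nu, params.RG
    U = (2 * nu + 1) * (2 * nu + 2) * q**2 * RG**2 / 6.0
    P = np.empty_like(U)

    small = U < 1e-8
    # P ~ 1 - U / ((1+2nu)(1+nu))  ==  1 - q² R_G²/3
    P[small] = 1.0 - U[small] / ((1 + 2 * nu) * (1 + nu))

    Ub = U[~small]
    a1, a2 = 1.0 / (2 * nu), 1.0 / nu
    P[~small] = (
        _lower_gamma(a1, Ub) / (nu * Ub**a1) - _lower_gamma(a2, Ub) / (nu * Ub**a2)
    )
    return params.scale * P + params.background


def fit_gauss_coil(
    curve: ScatteringCurve,
    init: GaussCoilParams | None = None,
    fit_background: bool = True,
) -> GaussCoilFit:
    """Weighted least-squares fit of the generalized Gaussian coil.

    Free parameters are (RG, nu, scale) and optionally a constant background.
    1-sigma errors come from the covariance of the weighted Levenberg-
    Marquardt fit; the goodness of fit is the reduced chi-square
    sum(((I - model)/sigma)^2)/(n - k).
    """
    if len(curve) < 10:
        raise ValueError("need at least 10 points to fit the form factor")
    if init is None:
        g = guinier_fit(curve, qmaxR_limit=1.3)
        rg0 = g.RGuinier if g.RGuinier > 1.0 else 30.0
        init = GaussCoilParams(RG=rg0, nu=0.5, scale=g.I0)

    q, I, sig = curve.q, curve.I, curve.sigma

    def model(qv, RG, nu, scale, background):
        return gauss_coil_formfactor(
            GaussCoilParams(RG=RG, nu=nu, scale=scale, background=background), qv
        )

    p0 = [init.RG, init.nu, init.scale, init.background]
    lo = [1e-3, 0.3, 1e-12, -np.inf]
    hi = [1e4, 1.0, np.inf, np.inf]
    if not fit_background:
        def model(qv, RG, nu, scale, _bg=init.background):  # noqa: F811
            return gauss_coil_formfactor(
                GaussCoilParams(RG=RG, nu=nu, scale=scale, background=_bg), qv
            )
        p0, lo, hi = p0[:3], lo[:3], hi[:3]

    try:
        popt, pcov = optimize.curve_fit(
            model, q, I, p0=p0, sigma=sig, absolute_sigma=True,
            bounds=(lo, hi), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"generalized Gaussian-coil fit did not converge (start {p0}): {err}"
        ) from err

    perr = np.sqrt(np.diag(pcov))
    # stderr fields bypass the parameter-domain validation on purpose
    errs = GaussCoilParams.__new__(GaussCoilParams)
    if fit_background:
        pars = GaussCoilParams(*popt)
        errs.RG, errs.nu, errs.scale, errs.background = perr
    else:
        pars = GaussCoilParams(*popt, background=init.background)
        errs.RG, errs.nu, errs.scale, errs.background = (*perr, 0.0)

    resid = (I - model(q, *popt)) / sig
    dof = max(len(curve) - len(popt), 1)
    return GaussCoilFit(
        params=pars, stderr=errs, covariance=pcov,
        chi2_red=float(resid @ resid) / dof, n_points=len(curve),
    )


# --------------------------------------------------------------------------- #
# Guinier analysis
# --------------------------------------------------------------------------- #

def guinier_fit(
    curve: ScatteringCurve,
    qmaxR_limit: float = 1.3,
    max_iter: int = 50,
    rtol: float = 1e-6,
) -> GuinierResult:
    """Iterative Guinier fit, self-consistent in the q_max*R_Guinier limit.

    Fits ln I = ln I0 - R² q²/3 (weighted by sigma/I) on q <= q_max and
    shrinks q_max until q_max * R_Guinier <= ``qmaxR_limit``.  The limit is
    1.1 for expanded chains and may be relaxed to 1.3 for compact states.
    """
    q, I, sig = curve.q, curve.I, curve.sigma
    pos = I > 0
    if pos.sum() < 5:
        raise ValueError("insufficient positive-intensity points for Guinier analysis")
    q, I, sig = q[pos], I[pos], sig[pos]

    def wls(mask):
        x, y, w = q[mask] ** 2, np.log(I[mask]), (I[mask] / sig[mask]) ** 2
        W = w.sum()
        xb, yb = (w * x).sum() / W, (w * y).sum() / W
        slope = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
        icept = yb - slope * xb
        R2 = -3.0 * slope
        return (np.sqrt(R2) if R2 > 0 else 0.0), np.exp(icept)

    # initial estimate from the lowest-q decade
    n0 = max(5, min(10, q.size))
    R, I0 = wls(np.arange(q.size) < n0)

    qmax = q[-1] if R == 0 else qmaxR_limit / R
    for _ in range(max_iter):
        mask = q <= qmax
        if mask.sum() < 5:
            raise ValueError(
                f"fewer than 5 points below q_max={qmax:.4g} 1/Å; "
                "Guinier range is insufficient"
            )
        R_new, I0 = wls(mask)
        if R_new == 0:
            R = 0.0
            break
        if abs(R_new - R) / R_new < rtol and q[mask][-1] * R_new <= qmaxR_limit + 1e-12:
            R = R_new
            break
        R = R_new
        qmax = qmaxR_limit / R
    mask = q <= qmax
    qmax_used = q[mask][-1]
    return GuinierResult(
        RGuinier=R, I0=I0, qmax_used=qmax_used, qmaxR=qmax_used * R,
        n_points=int(mask.sum()), below_resolution=qmax_used * R < 0.2,
    )


def kratky_transform(curve: ScatteringCurve):
    """Kratky transform (q, q² I) with errors propagated as q² sigma."""
    return curve.q.copy(), curve.q**2 * curve.I, curve.q**2 * curve.sigma


# --------------------------------------------------------------------------- #
# structure factor
# --------------------------------------------------------------------------- #

def estimate_structure_factor(
    concentrated: ScatteringCurve,
    dilute: ScatteringCurve,
    c_conc: float | None = None,
    c_dil: float | None = None,
) -> StructureFactorCurve:
    """S(q) from a concentration pair: (I_conc/c_conc) / (I_dil/c_dil).

    The dilute curve is interpolated onto the concentrated grid linearly in
    ln I; points outside the dilute q-support are dropped, never
    extrapolated.  Uncertainties follow quotient propagation.  Points where
    the dilute intensity is non-positive are masked with a warning.
    """
    if c_conc is None:
        c_conc = concentrated.meta.get("concentration", 1.0)
    if c_dil is None:
        c_dil = dilute.meta.get("concentration", 1.0)

    inside = (concentrated.q >= dilute.q[0]) & (concentrated.q <= dilute.q[-1])
    q = concentrated.q[inside]
    Ic, sc = concentrated.I[inside], concentrated.sigma[inside]

    ok_d = dilute.I > 0
    if not ok_d.all():
        warnings.warn(
            f"{(~ok_d).sum()} dilute points with I<=0 masked in S(q) estimation"
        )
    qd, Id_, sd = dilute.q[ok_d], dilute.I[ok_d], dilute.sigma[ok_d]
    Id = np.exp(np.interp(q, qd, np.log(Id_)))
    rel_d = np.interp(q, qd, sd / Id_)

    good = Ic > 0
    if not good.all():
        warnings.warn(f"{(~good).sum()} concentrated points with I<=0 masked")
    q, Ic, sc, Id, rel_d = q[good], Ic[good], sc[good], Id[good], rel_d[good]

    S = (Ic / c_conc) / (Id / c_dil)
    sigma = S * np.sqrt((sc / Ic) ** 2 + rel_d**2)
    return StructureFactorCurve(q=q, S=S, sigma=sigma,
                                meta={"c_conc": c_conc, "c_dil": c_dil})


# Taylor coefficients (in A^2) of the three PY kernels, derived symbolically:
#   g1 = (sin A - A cos A)/A^3
#   g2 = (2 A sin A + (2 - A^2) cos A - 2)/A^4
#   g3 = (-A^4 cos A + 4((3A^2-6) cos A + (A^3-6A) sin A + 6))/A^6
_G1 = [1 / 3, -1 / 30, 1 / 840, -1 / 45360, 1 / 3991680, -1 / 518918400]
_G2 = [1 / 4, -1 / 36, 1 / 960, -1 / 50400, 1 / 4354560, -1 / 558835200]
_G3 = [1 / 6, -1 / 48, 1 / 1200, -1 / 60480, 1 / 5080320, -1 / 638668800]


def _py_kernels(A: np.ndarray):
    """The three oscillatory kernels of the PY direct correlation function.

    Below A = 0.9 the closed forms suffer catastrophic cancellation and a
    10th-order Taylor series (relative error < 1e-12 there) is used instead.
    """
    A = np.asarray(A, dtype=float)
    g = np.empty((3,) + A.shape)
    small = A < 0.9
    A2s = A[small] ** 2
    for i, coeffs in enumerate((_G1, _G2, _G3)):
        g[i, small] = sum(c * A2s**k for k, c in enumerate(coeffs))
    Ab = A[~small]
    s, c = np.sin(Ab), np.cos(Ab)
    g[0, ~small] = (s - Ab * c) / Ab**3
    g[1, ~small] = (2 * Ab * s + (2 - Ab**2) * c - 2) / Ab**4
    g[2, ~small] = (-(Ab**4) * c + 4 * ((3 * Ab**2 - 6) * c + (Ab**3 - 6 * Ab) * s + 6)) / Ab**6
    return g


def hard_sphere_sq(params: HardSphereParams, q) -> np.ndarray:
    """Percus-Yevick structure factor of non-charged hard spheres.

    Analytic solution of the PY closure for hard spheres of radius ``R_hs``
    at volume fraction ``phi``; S(0) = (1-phi)^4/(1+2 phi)^2 and S -> 1 for
    q R_hs -> infinity.
    """
    phi = params.phi
    q = np.asarray(q, dtype=float)
    if phi == 0.0:
        return np.ones_like(q)
    A = 2.0 * params.R_hs * q
    denom = (1 - phi) ** 4
    alpha = (1 + 2 * phi) ** 2 / denom
    beta = -6 * phi * (1 + phi / 2) ** 2 / denom
    gamma_ = phi * alpha / 2
    g1, g2, g3 = _py_kernels(A)
    C = 24 * phi * (alpha * g1 + beta * g2 + gamma_ * g3)
    return 1.0 / (1.0 + C)


def fit_hard_sphere(
    sq: StructureFactorCurve, init: HardSphereParams | None = None
) -> HardSphereFit:
    """Weighted fit of the PY hard-sphere model to a structure factor."""
    if init is None:
        init = HardSphereParams(R_hs=30.0, phi=0.05)
    q, S, sig = sq.q, sq.S, sq.sigma

    def model(qv, R_hs, phi):
        return hard_sphere_sq(HardSphereParams(R_hs=max(R_hs, 1e-6), phi=phi), qv)

    popt, pcov = optimize.curve_fit(
        model, q, S, p0=[init.R_hs, init.phi], sigma=sig, absolute_sigma=True,
        bounds=([1e-3, 0.0], [1e4, 0.7399]), maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    resid = (S - model(q, *popt)) / sig
    dof = max(q.size - 2, 1)
    stderr = HardSphereParams.__new__(HardSphereParams)
    stderr.R_hs, stderr.phi = perr
    return HardSphereFit(
        params=HardSphereParams(*popt), stderr=stderr,
        chi2_red=float(resid @ resid) / dof,
    )


def stiff_segment_q(lp: float) -> float:
    """Reciprocal-space marker q* = 1.91/l_p of the stiff chain segment.

    ``lp`` is the persistence length in Å; q* is returned in 1/Å.
    """
    if lp <= 0:
        raise ValueError("persistence length must be positive")
    return 1.91 / lp
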