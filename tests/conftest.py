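"""Shared fixtures: small synthetic inputs, session-scoped heavy objects."""

import numpy as np
import pytest

from coildyn.chains import Ensemble, generate_ensemble
from coildyn.nmodes import build_nm_model
from coildyn.sas import GaussCoilParams, ScatteringCurve, gauss_coil_formfactor

SEED = 20260929


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def gauss_curve_exact():
    """Noise-free generalized-Gaussian-coil curve, RG=45 Å, nu=0.53."""
    q = np.geomspace(0.01, 0.5, 80)
    p = GaussCoilParams(RG=45.0, nu=0.53)
    I = gauss_coil_formfactor(p, q)
    return ScatteringCurve(q, I, 0.02 * I), p


@pytest.fixture(scope="session")
def ideal_ensemble():
    """500 ideal chains of 169 beads (nu = 1/2)."""
    return generate_ensemble(500, 169, 0.5, seed=SEED)


@pytest.fixture(scope="session")
def expanded_nm_ensemble():
    """Expanded, slowly rotating conformers used as NM substrate."""
    big = generate_ensemble(30, 169, 0.65, seed=5)
    return Ensemble([c for c in big.chains if c.rg > 30][:6])


@pytest.fixture(scope="session")
def nm_model(expanded_nm_ensemble):
    q = np.array([0.08, 0.11, 0.14, 0.17, 0.20, 0.24, 0.28, 0.32])
    return build_nm_model(expanded_nm_ensemble, q, eta=1.1, T=295.0)
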