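"""Internal unit system: lengths in Å, times in ns, viscosities in mPa·s, T in K.

With these units the Boltzmann constant is

    k_B = 1.380649e-23 J/K = 13.80649 (mPa·s·Å³)/(ns·K)

because 1 mPa·s·Å³/ns = 1e-3 · 1e-30 / 1e-9 J = 1e-24 J.  All diffusion
coefficients then come out in Å²/ns and all relaxation times in ns without
further conversion factors.
"""

KB = 13.80649  # Boltzmann constant [mPa·s·Å³ / (ns·K)]

NM_PER_ANGSTROM = 0.1


def kBT(T: float) -> float:
    """Thermal energy at temperature ``T`` [K] in mPa·s·Å³/ns."""
    return KB * T
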