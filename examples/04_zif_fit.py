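"""Fit the Zimm-with-internal-friction model to a spin-echo dataset.

Generates a synthetic NSE dataset from the ZIF forward model (internal
friction time tau_i = 70 ns, the compact-state scale) and fits it globally
with both the ZIF and the pure Zimm model.
"""

from coildyn.synthetic import make_nse_zif
from coildyn.zimm import ZimmParams, fit_nse_zif, fit_stretched_exponential

params = ZimmParams(RG=40.0, nu=0.48, eta=1.1, T=295.0, N=20, tau_i=70.0)
print(f"chain: Re = {params.Re:.1f} Å, first Zimm time tau_1 = "
      f"{params.tau_zimm:.1f} ns")

ds, truth = make_nse_zif(params, D0t=4.0, H=1.2, noise_frac=0.02, seed=7)

kww = fit_stretched_exponential(ds)
print(f"model-free: <beta> = {kww.beta_mean:.2f} "
      "(1 = simple exponential, 0.85 = ideal Zimm)")

res = fit_nse_zif(ds, params, D0t=4.0)
print(f"ZIF fit:  tau_i = {res.tau_i:.1f} ± {res.tau_i_err:.1f} ns  "
      f"H = {res.H:.2f} ± {res.H_err:.2f}  chi2_red = {res.chi2_red:.2f}")
print(f"Zimm fit (tau_i = 0): chi2_red = {res.chi2_red_zimm:.1f}")
print()
print("The internal-friction time is recovered from the data; the pure Zimm")
print("model, which lets every mode relax at its solvent-driven rate, fails")
print("by an order of magnitude in chi2 — the signature of internal friction")
print("in compact disordered chains.")
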