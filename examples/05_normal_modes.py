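"""Normal-mode analysis of a spin-echo dataset on a conformer ensemble.

Computes ANM modes and multipole form-factor tables for expanded
conformers, generates NSE data from the rigid-body + internal-mode forward
model, refits (RMSD, tau_NM, H) and converts to a Brownian-oscillator
friction.
"""

import numpy as np

from coildyn.chains import Ensemble, generate_ensemble
from coildyn.nmodes import brownian_friction, build_nm_model, fit_nse_nm
from coildyn.synthetic import make_nse_nm

big = generate_ensemble(30, 169, 0.65, seed=5)
ens = Ensemble([c for c in big.chains if c.rg > 30][:6])
print(f"NM substrate: {len(ens)} expanded conformers, R_G = "
      f"{np.round(ens.rgs(), 1)} Å")

q = np.array([0.08, 0.11, 0.14, 0.17, 0.20, 0.24, 0.28, 0.32])
model = build_nm_model(ens, q, eta=1.1, T=295.0)
print(f"rotational correlation times: {np.round(1/(6*model.Dr), 1)} ns")

t = np.logspace(-1, np.log10(200), 25)
ds, truth = make_nse_nm(model, D0t=3.2, RMSD=4.5, tau_NM=7.0, H=1.0,
                        t=t, noise_frac=0.02, seed=13)
res = fit_nse_nm(ds, model, D0t=3.2)
fr = brownian_friction(res.RMSD, res.tau_NM, 295.0)

print(f"truth:  RMSD = 4.50 Å  tau_NM = 7.0 ns  H = 1.00")
print(f"fitted: RMSD = {res.RMSD:.2f} ± {res.RMSD_err:.2f} Å  "
      f"tau_NM = {res.tau_NM:.1f} ± {res.tau_NM_err:.1f} ns  "
      f"H = {res.H:.2f}  chi2_red = {res.chi2_red:.2f}")
print(f"Brownian oscillator: k = {fr.k:.3f} kBT/Å², "
      f"zeta = {fr.zeta:.3f} kBT·ns/Å²")
print()
print("Larger mode amplitudes at constant relaxation time mean lower internal")
print("friction zeta = kBT tau/RMSD² — the normal-mode counterpart of a")
print("decreasing ZIF internal-friction time.")
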