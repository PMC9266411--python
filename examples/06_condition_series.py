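"""Run the full pipeline over the synthetic denaturant condition series.

Five conditions emulate the compact -> expanded transition of a disordered
protein under increasing denaturant: the pipeline fits (R_G, nu) from
small-angle curves, tau_i and H from ZIF fits, (RMSD, tau_NM) from
normal-mode fits and reports the Brownian-oscillator friction.
"""

import pandas as pd

from coildyn.io import RunConfig
from coildyn.pipeline import run_pipeline

pd.set_option("display.width", 160)

config = RunConfig(seed=3, n_chains=12, outdir="scratch/pipeline_out")
report = run_pipeline(config)

cols = ["label", "RG", "nu", "tau_i", "H_zif", "chi2_zimm", "chi2_zif",
        "RMSD", "tau_NM", "zeta"]
print(report[cols].round(3).to_string(index=False))
print()
print("Along the series: nu rises (chain statistics swell), the ZIF internal-")
print("friction time falls toward its ~40 ns floor, normal-mode amplitudes")
print("(RMSD) grow at roughly constant tau_NM, and the Brownian-oscillator")
print("friction zeta drops — expansion releases internal friction.")
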