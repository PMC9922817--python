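"""Simulate three-channel pSILAC evidence with known turnover ground truth.

Builds a small screen (100 proteins: 13 with a strong synthesis block
emulating mitochondrially encoded subunits under drug, 10 milder planted
effects, the rest null), prints a few evidence rows, and shows that in the
noiseless limit every peptide's H/M ratio equals the protein's closed-form
kinetic ratio.
"""

import dataclasses

import numpy as np

from mitopulse import NO_NOISE, channel_amounts_psilac, default_psilac_scenario

scenario = default_psilac_scenario(seed=11, n_proteins=100, n_mt=13, n_orphans=10)
evidence = scenario.generate()
print(f"evidence rows: {len(evidence)} "
      f"({evidence.protein_id.nunique()} proteins x {evidence.replicate_id.nunique()} replicates)")
print(evidence.head(4).to_string(index=False))

# noiseless limit: ratios are exactly the closed-form kinetics
noiseless = dataclasses.replace(scenario, noise=NO_NOISE)
ev0 = noiseless.generate()
pid = "MT01"
p = scenario.params[pid]
rows = ev0[(ev0.protein_id == pid) & (ev0.replicate_id == "r1")]
expected = (channel_amounts_psilac(p, scenario.design, True)[1]
            / channel_amounts_psilac(p, scenario.design, False)[1])
print(f"\n{pid}: closed-form H/M = {expected:.4f}; "
      f"noiseless peptide H/M = {np.unique(rows.intensity_H / rows.intensity_M)}")
print("log2 H/M =", np.log2(expected).round(3),
      "-> the planted synthesis block (f=0.05) suppresses the new cohort.")
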