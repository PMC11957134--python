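"""Estimate allelic dropout and BAF distortion of two WGA chemistries.

Simulates germline het-SNP read counts for a PTA-like cell (low dropout,
mild imbalance) and an MDA-like cell (high dropout, strong imbalance) and
runs the per-cell QC estimators on each.
"""

import pandas as pd
import numpy as np

import clonescope as cs
from clonescope.qc import baf_summary

het = cs.simulate_het_snp_positions(20_000, seed=0)
cell = pd.DataFrame(np.zeros((1, 1)), index=["cell"], columns=["m"])

for name, profile in (("PTA-like", cs.PTA_PROFILE), ("MDA-like", cs.MDA_PROFILE)):
    depths = cs.simulate_wga_readcounts(cell, profile,
                                        het_snp_positions=het, seed=2)
    ado = cs.estimate_ado(depths)
    baf = baf_summary(depths)
    recall = cs.estimate_recall_germline(depths, het)
    print(f"{name}: ADO {ado:.3f} (truth {profile.ado_rate}), "
          f"BAF variance {baf['baf_var']:.4f}, germline recall {recall:.3f}")

print("\nThe MDA-like chemistry loses ~3x more alleles and spreads the "
      "het-site BAF density much wider — the reason PTA-grade data are "
      "needed for 5-kb-scale CNV calling and deep phylogenies.")
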