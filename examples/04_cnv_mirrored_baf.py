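"""Call a clone-restricted hemizygous deletion from mirrored BAF windows.

Simulates 16 PTA-like cells in two clones, injects a 70x5-kb deletion into
one clone, computes per-(cell, window) mirrored BAF, and evaluates the
threshold caller with a cell-bootstrap ROC against clone truth.
"""

import clonescope as cs

truth, G = cs.simulate_clone_tree(16, 2, 2.0, sampling_schedule=[30, 40],
                                  cells_per_clone=[8, 8], seed=4)
span = 70 * 5000
het = cs.simulate_het_snp_positions(int(span / 1200), chrom="chr13",
                                    start=0, end=span, seed=5)
depths = cs.simulate_wga_readcounts(G, cs.PTA_PROFILE,
                                    het_snp_positions=het, seed=6)
event = cs.CnvEvent(clone=1, chrom="chr13", start=0, end=span)
depths = cs.inject_cnv(depths, truth, event, seed=7)

matrix = cs.window_mirrored_baf(depths, w=5000)
carrier = {c: truth.clone_of_cell[c] == 1 for c in matrix.cells}
roc = cs.roc_evaluate(matrix, carrier, n_bootstrap=100, seed=8)

import numpy as np
carr = [i for i, c in enumerate(matrix.cells) if carrier[c]]
noncarr = [i for i, c in enumerate(matrix.cells) if not carrier[c]]
print(f"windows: {matrix.values.shape[1]} x 5 kb, "
      f"mean mirrored BAF carriers {np.nanmean(matrix.values[carr]):.3f} "
      f"vs non-carriers {np.nanmean(matrix.values[noncarr]):.3f}")
print(f"ROC AUC = {roc.auc:.3f} +/- {roc.auc_sd:.3f} (cell bootstrap)")
print("Near-1 AUC at 5-kb windows: one lost haplotype pins the carrier "
      "windows' mirrored BAF at ~1 while balanced windows sit near 0.6.")
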