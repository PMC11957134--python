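"""Simulate a serial clone-expansion experiment and inspect the truth.

Builds the 16-cell benchmark design (2 parental cells + 2 cells from each
of 7 subclones sampled at weekly intervals), with mutations accumulating
Poisson-proportionally to culture time.
"""

import clonescope as cs

truth, genotypes = cs.simulate_clone_tree(
    **cs.invitro_benchmark_design(), mutations_per_day=4.0, seed=1)

print(f"cells: {genotypes.shape[0]}, truth mutations: {genotypes.shape[1]}")
print("\nculture days and mutation count per cell:")
for cell in truth.cells:
    days = truth.culture_time_of_cell[cell]
    n_mut = int(genotypes.loc[cell].sum())
    print(f"  {cell:10s}  clone {truth.clone_of_cell[cell]}  "
          f"{days:5.0f} d  {n_mut:4d} mutations")

print("\nLonger-cultured clones carry more mutations: the root-to-tip "
      "mutation count is the molecular clock the phylogeny stages read out.")
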