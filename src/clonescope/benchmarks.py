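"""Scaled-down synthetic benchmarks of the two headline pipeline metrics.

Both emulate the in vitro serial clone-expansion validation design: 16
PTA-amplified cells (two parental plus two per subclone), mutations
accumulating Poisson-proportionally to culture days, and a hemizygous
deletion restricted to one clone.  Each benchmark simulates the data,
runs the corresponding caller end to end, and averages the metric over
independent seeds.
"""

from __future__ import annotations

import numpy as np

from . import cnv as cnv_mod
from . import trees as tree_mod
from .simulate import (CnvEvent, PTA_PROFILE, as_rng, inject_cnv,
                       genotype_calls_from_depths, invitro_benchmark_design,
                       simulate_clone_tree, simulate_het_snp_positions,
                       simulate_wga_readcounts)

__all__ = ["cnv_auc_benchmark", "branch_time_correlation_benchmark"]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1, dtype=np.uint32)[0]) for s in ss.spawn(n)]


def cnv_auc_benchmark(seed: int = 0, n_seeds: int = 10,
                      n_windows_deleted: int = 70, window_bp: int = 5000,
                      snp_per_kb: float = 1.0 / 1.2,
                      n_bootstrap: int = 100) -> dict:
    """Mirrored-BAF CNV caller ROC AUC at 5-kb windows on PTA-like data.

    Two clones of 8 cells each; carrier-clone cells harbor a hemizygous
    deletion spanning ``n_windows_deleted`` contiguous windows; het-SNP
    allele depths are simulated at ~30x with PTA-like dropout.  The ROC
    sweeps fixed BAF thresholds over all qc-passing windows in the region
    with truth labels following clone membership.  Returns the per-seed
    AUCs and their mean.
    """
    aucs = []
    for s in _child_seeds(seed, n_seeds):
        rng = as_rng(s)
        truth, G = simulate_clone_tree(
            n_cells=16, n_clones=2, mutations_per_day=2.0,
            sampling_schedule=[30.0, 40.0], cells_per_clone=[8, 8],
            seed=rng)
        span = n_windows_deleted * window_bp
        n_snps = int(span * snp_per_kb / 1000)
        het = simulate_het_snp_positions(n_snps, chrom="chr13", start=0,
                                         end=span, seed=rng)
        depths = simulate_wga_readcounts(G, PTA_PROFILE,
                                         het_snp_positions=het, seed=rng)
        event = CnvEvent(clone=1, chrom="chr13", start=0, end=span)
        depths = inject_cnv(depths, truth, event, seed=rng)
        matrix = cnv_mod.window_mirrored_baf(depths, w=window_bp)
        carrier = {c: truth.clone_of_cell[c] == event.clone
                   for c in matrix.cells}
        roc = cnv_mod.roc_evaluate(matrix, carrier, n_bootstrap=n_bootstrap,
                                   seed=rng)
        aucs.append(roc.auc)
    return {"auc_mean": float(np.mean(aucs)), "auc_per_seed": aucs,
            "n_cells": 16, "n_windows": n_windows_deleted}


def branch_time_correlation_benchmark(seed: int = 0, n_seeds: int = 10,
                                      mutations_per_day: float = 4.0,
                                      n_perm: int = 2000) -> dict:
    """Root-to-tip branch length vs culture time on the 16-cell design.

    Seven subclones sampled at weekly intervals plus two parental cells;
    per-branch mutation counts are Poisson with mean proportional to
    elapsed days; PTA-like dropout distorts the observed genotypes; the
    tree is reconstructed by neighbor-joining and the Spearman
    correlation of root-to-tip path length vs culture days computed.
    Returns per-seed rho values and their mean.
    """
    rhos, pvals = [], []
    for s in _child_seeds(seed, n_seeds):
        rng = as_rng(s)
        truth, G = simulate_clone_tree(**invitro_benchmark_design(),
                                       mutations_per_day=mutations_per_day,
                                       seed=rng)
        depths = simulate_wga_readcounts(G, PTA_PROFILE, seed=rng)
        calls = genotype_calls_from_depths(depths)
        tree = tree_mod.build_tree(calls)
        res = tree_mod.correlate_branch_time(tree, truth.culture_time_of_cell,
                                             n_perm=n_perm, seed=rng)
        rhos.append(res["rho"])
        pvals.append(res["p_perm"])
    return {"rho_mean": float(np.mean(rhos)), "rho_per_seed": rhos,
            "p_perm": pvals, "n_cells": 16}
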