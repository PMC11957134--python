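"""End-to-end orchestration of the synthetic-to-report workflow.

``run_pipeline`` chains simulation -> per-cell QC -> clonal calling ->
mirrored-BAF CNV + ROC -> tree + bootstrap -> time calibration + skyline
-> ABC clone dynamics -> signatures, with per-stage toggles.  A single
top-level seed fans out to per-stage child seeds through a counter-based
spawn, so toggling one stage never shifts another stage's random stream.
Every stage writes its outputs in standard text formats and the run ends
with a machine-readable JSON summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import io as cio
from . import qc as qc_mod
from . import signatures as sig_mod
from . import trees as tree_mod
from .simulate import (CnvEvent, PTA_PROFILE, inject_cnv,
                       genotype_calls_from_depths, simulate_clone_tree,
                       simulate_het_snp_positions, simulate_phenotypes,
                       simulate_wga_readcounts)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("clonescope")

#: fixed per-stage offsets; independent of which stages are enabled
_STAGE_IDS = {"simulate": 0, "qc": 1, "clonal": 2, "cnv": 3, "tree": 4,
              "timecal": 5, "skyline": 6, "abc": 7, "signatures": 8,
              "treatment": 9}


def stage_seed(seed: int, stage: str) -> int:
    """Counter-based child seed for a stage; stable under stage toggling."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_IDS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration (config + seed -> outputs)."""

    seed: int = 0
    outdir: str = "clonescope_run"
    # simulation
    n_cells: int = 16
    n_clones: int = 8
    mutations_per_day: float = 4.0
    sampling_schedule: list = field(default_factory=lambda: [10.0, 25.0, 32.0, 39.0, 46.0, 53.0, 60.0, 67.0])
    cells_per_clone: list | None = field(default_factory=lambda: [2] * 8)
    n_het_snps: int = 2000
    cnv_clone: int = 7
    cnv_span_windows: int = 60
    window_bp: int = 5000
    n_markers: int = 3
    bm_rate: float = 1.0
    noise_sd: float = 0.2
    # stage toggles
    run_qc: bool = True
    run_clonal: bool = True
    run_cnv: bool = True
    run_tree: bool = True
    run_timecal: bool = True
    run_skyline: bool = True
    run_abc: bool = False
    run_signatures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = cio.read_yaml(path) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        cio.write_yaml(asdict(self), path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; returns a summary dict (also on disk).

    Stage failures halt downstream dependents; outputs of completed
    stages are retained.  Reruns with the same config + seed reproduce
    numerically identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "stages": {}}

    # --- simulate ------------------------------------------------------
    s_seed = stage_seed(config.seed, "simulate")
    truth, genotypes = simulate_clone_tree(
        config.n_cells, config.n_clones, config.mutations_per_day,
        sampling_schedule=config.sampling_schedule,
        cells_per_clone=config.cells_per_clone, seed=s_seed)
    het = simulate_het_snp_positions(config.n_het_snps, seed=s_seed + 1)
    depths = simulate_wga_readcounts(genotypes, PTA_PROFILE,
                                     het_snp_positions=het, seed=s_seed + 2)
    cnv_event = None
    if config.cnv_span_windows > 0:
        span = config.cnv_span_windows * config.window_bp
        start = int(het["pos"].quantile(0.2) // config.window_bp) * config.window_bp
        cnv_event = CnvEvent(clone=config.cnv_clone, chrom=str(het["chrom"].iloc[0]),
                             start=start, end=start + span)
        depths = inject_cnv(depths, truth, cnv_event, seed=s_seed + 3)
    somatic = simulate_wga_readcounts(genotypes, PTA_PROFILE, seed=s_seed + 4)
    phen = simulate_phenotypes(truth.tree, config.n_markers, config.bm_rate,
                               config.noise_sd, seed=s_seed + 5)
    truth_variants = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(genotypes.shape[1]),
        "id": list(genotypes.columns), "ref": "C", "alt": "T"})
    cio.write_vcf(truth_variants, out / "truth_variants.vcf")
    cio.write_tsv(depths, out / "het_allele_depths.tsv")
    cio.write_newick(truth.tree, out / "truth_tree.nwk")
    if cnv_event is not None:
        cio.write_bed(pd.DataFrame([{"chrom": cnv_event.chrom,
                                     "start": cnv_event.start,
                                     "end": cnv_event.end,
                                     "name": f"clone{cnv_event.clone}_del"}]),
                      out / "cnv_truth.bed")
    cio.write_tsv(phen.reset_index(names="cell"), out / "phenotypes.tsv")
    summary["stages"]["simulate"] = {"n_cells": config.n_cells,
                                     "n_variants": int(genotypes.shape[1])}

    calls = genotype_calls_from_depths(somatic)

    # --- qc ------------------------------------------------------------
    if config.run_qc:
        reports = []
        for cell, grp in depths.groupby("cell"):
            ado = qc_mod.estimate_ado(grp)
            b = qc_mod.baf_summary(grp)
            reports.append({"cell": cell, "ado_rate": ado, **b})
        qc_df = pd.DataFrame(reports)
        cio.write_tsv(qc_df, out / "cell_qc.tsv")
        summary["stages"]["qc"] = {"mean_ado": float(qc_df["ado_rate"].mean())}

    # --- clonal calling -------------------------------------------------
    if config.run_clonal:
        clone_sets = {}
        for clone in sorted(set(truth.clone_of_cell.values())):
            cells = [c for c, k in truth.clone_of_cell.items() if k == clone]
            if len(cells) < 2:
                continue
            per_cell = {c: set(calls.columns[calls.loc[c] == 1]) for c in cells}
            clone_sets[clone] = qc_mod.call_clonal_mutations(per_cell)
        summary["stages"]["clonal"] = {str(k): len(v) for k, v in clone_sets.items()}

    # --- cnv ------------------------------------------------------------
    if config.run_cnv and cnv_event is not None:
        matrix = cnv_mod.window_mirrored_baf(depths, w=config.window_bp)
        region = ((matrix.windows["start"] >= cnv_event.start)
                  & (matrix.windows["end"] <= cnv_event.end)).to_numpy()
        sub = cnv_mod.BafWindowMatrix(
            cells=matrix.cells, windows=matrix.windows[region].reset_index(drop=True),
            values=matrix.values[:, region], qc_pass=matrix.qc_pass[:, region],
            min_snps=matrix.min_snps, min_cells=matrix.min_cells)
        carrier = {c: truth.clone_of_cell[c] == cnv_event.clone for c in matrix.cells}
        roc = cnv_mod.roc_evaluate(sub, carrier, seed=stage_seed(config.seed, "cnv"))
        cio.write_tsv(pd.DataFrame({"threshold": roc.thresholds,
                                    "tpr": roc.tpr, "fpr": roc.fpr}),
                      out / "cnv_roc.tsv")
        summary["stages"]["cnv"] = {"auc": roc.auc, "auc_sd": roc.auc_sd}

    # --- tree -----------------------------------------------------------
    tree = None
    if config.run_tree:
        tree, support = tree_mod.bootstrap_support(
            calls, n_reps=50, seed=stage_seed(config.seed, "tree"))
        cio.write_newick(tree, out / "cell_tree.nwk")
        corr = tree_mod.correlate_branch_time(
            tree, truth.culture_time_of_cell, n_perm=2000,
            seed=stage_seed(config.seed, "tree") + 1)
        summary["stages"]["tree"] = {
            "rho_time": corr["rho"], "p_perm": corr["p_perm"],
            "min_support": min(support.values()) if support else None}

    # --- time calibration + skyline --------------------------------------
    if config.run_timecal and tree is not None:
        mut_tree = tree
        anchors = {c: (t / 365.0) for c, t in truth.culture_time_of_cell.items()}
        tt = tree_mod.time_calibrate(mut_tree, anchors=anchors, n_samples=300,
                                     seed=stage_seed(config.seed, "timecal"))
        ages = tt.node_age_summary()
        cio.write_tsv(ages.reset_index(names="node"), out / "node_ages.tsv")
        summary["stages"]["timecal"] = {
            "rate_mean": float(tt.rate_samples.mean())}
        if config.run_skyline:
            sky = tree_mod.skyline_ne(tt)
            cio.write_tsv(sky, out / "skyline.tsv")
            summary["stages"]["skyline"] = {"n_epochs": int(len(sky))}

    # --- signatures -------------------------------------------------------
    if config.run_signatures:
        rng = np.random.default_rng(stage_seed(config.seed, "signatures"))
        catalogue = sig_mod.synthetic_reference_catalogue()
        mix = np.array([0.6, 0.3, 0.1])
        probs = (catalogue.to_numpy() @ mix)
        n_var = genotypes.shape[1]
        cats = rng.choice(96, size=n_var, p=probs / probs.sum())
        var_rows = []
        for i, ci in enumerate(cats):
            cat = sig_mod.SBS96_CATEGORIES[ci]
            ref = cat[2]
            alt = cat[4]
            var_rows.append({"sample": "synthetic", "ref": ref, "alt": alt,
                             "context": cat[0] + ref + cat[6]})
        m = sig_mod.sbs96_matrix(pd.DataFrame(var_rows))
        fit = sig_mod.fit_signatures(m, catalogue, normalize=True)
        cio.write_tsv(fit["exposures"].reset_index(names="signature"),
                      out / "signature_exposures.tsv")
        summary["stages"]["signatures"] = {
            "cosine": float(fit["cosine"].iloc[0])}

    cio.write_json(summary, out / "run_summary.json")
    return summary
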