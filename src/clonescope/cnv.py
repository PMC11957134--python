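"""Mirrored-BAF windowed copy-number detection from het-SNP allele depths.

A hemizygous deletion removes one haplotype, so the B-allele frequency of
germline het SNPs in the region collapses to ~0 or ~1.  Folding the BAF to
its mirrored form max(BAF, 1-BAF) turns symmetric amplification noise into
a one-sided imbalance score; averaging over fixed genomic windows (default
5 kb) and thresholding yields per-cell CNV calls, evaluated here by a
cell-bootstrap ROC against clone-level truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import as_rng

__all__ = [
    "BafWindowMatrix",
    "window_mirrored_baf",
    "call_cnv_threshold",
    "roc_evaluate",
    "RocResult",
]


@dataclass
class BafWindowMatrix:
    """Cells x genomic windows of mirrored BAF with QC flags.

    windows : DataFrame (chrom, start, end), half-open, width ``w``
    values : float array (n_cells, n_windows); NaN where undefined
    qc_pass : bool array, same shape; a window must hold >=
        ``min_snps`` qualifying SNPs in a cell to pass
    """

    cells: list
    windows: pd.DataFrame
    values: np.ndarray
    qc_pass: np.ndarray
    min_snps: int = 3
    min_cells: int = 5

    def __post_init__(self):
        defined = self.qc_pass & ~np.isnan(self.values)
        v = self.values[defined]
        if v.size and ((v < 0.5 - 1e-9) | (v > 1.0 + 1e-9)).any():
            raise ValueError("mirrored BAF outside [0.5, 1]")

    @property
    def eligible_windows(self) -> np.ndarray:
        """Windows qc-passing in at least ``min_cells`` cells."""
        return self.qc_pass.sum(axis=0) >= self.min_cells

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{r.chrom}:{r.start}-{r.end}" for r in self.windows.itertuples()]
        return pd.DataFrame(self.values, index=self.cells, columns=labels)


def window_mirrored_baf(allele_depths: pd.DataFrame,
                        het_snps: pd.DataFrame | None = None,
                        w: int = 5000,
                        min_snps_per_window: int = 3,
                        min_depth: int = 8,
                        min_cells: int = 5) -> BafWindowMatrix:
    """Average mirrored BAF of het SNPs within fixed windows, per cell.

    Per SNP with total depth >= ``min_depth``: BAF = alt/(alt+ref) and
    mirrored BAF = max(BAF, 1-BAF).  Window value = mean over qualifying
    SNPs; windows holding fewer than ``min_snps_per_window`` such SNPs in
    a cell are flagged qc_fail there (value NaN when no SNP at all).
    Windows are 0-based half-open of width ``w`` tiling each chromosome
    from coordinate 0.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    df = allele_depths
    if het_snps is not None:
        key = pd.MultiIndex.from_frame(het_snps[["chrom", "pos"]])
        df = df[pd.MultiIndex.from_frame(df[["chrom", "pos"]]).isin(key)]
    df = df.copy()
    if (df[["ref_depth", "alt_depth"]] < 0).any().any():
        raise ValueError("negative depths")
    total = df["ref_depth"] + df["alt_depth"]
    df = df[total >= min_depth].copy()
    tot = df["ref_depth"] + df["alt_depth"]
    baf = df["alt_depth"] / tot
    df["mbaf"] = np.maximum(baf, 1.0 - baf)
    df["win"] = (df["pos"] // w).astype(int)

    cells = sorted(allele_depths["cell"].unique())
    win_keys = (df[["chrom", "win"]].drop_duplicates()
                .sort_values(["chrom", "win"]).reset_index(drop=True))
    windows = pd.DataFrame({"chrom": win_keys["chrom"],
                            "start": win_keys["win"] * w,
                            "end": (win_keys["win"] + 1) * w})
    widx = {(r.chrom, r.win): i for i, r in enumerate(win_keys.itertuples())}
    cidx = {c: i for i, c in enumerate(cells)}

    values = np.full((len(cells), len(windows)), np.nan)
    counts = np.zeros((len(cells), len(windows)), dtype=int)
    grp = df.groupby(["cell", "chrom", "win"])["mbaf"].agg(["mean", "size"])
    for (cell, chrom, win), row in grp.iterrows():
        i, j = cidx[cell], widx[(chrom, win)]
        values[i, j] = row["mean"]
        counts[i, j] = int(row["size"])
    qc_pass = counts >= min_snps_per_window
    return BafWindowMatrix(cells=cells, windows=windows, values=values,
                           qc_pass=qc_pass, min_snps=min_snps_per_window,
                           min_cells=min_cells)


def call_cnv_threshold(matrix: BafWindowMatrix, threshold: float) -> np.ndarray:
    """Boolean imbalance calls: window value >= threshold and qc-passing."""
    if not (0.5 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0.5, 1]")
    with np.errstate(invalid="ignore"):
        return matrix.qc_pass & (np.nan_to_num(matrix.values, nan=-1.0) >= threshold)


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_bootstrap: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr_band: np.ndarray | None = None  # (2, n_thresholds): mean +/- 2 sd
    fpr_band: np.ndarray | None = None

    @property
    def auc_sd(self) -> float:
        return float(self.auc_bootstrap.std(ddof=1)) if self.auc_bootstrap.size > 1 else np.nan


def _rates(calls: np.ndarray, qc: np.ndarray, carrier: np.ndarray):
    pos = carrier[:, None] & qc
    neg = ~carrier[:, None] & qc
    tpr = calls[pos].mean() if pos.any() else np.nan
    fpr = calls[neg].mean() if neg.any() else np.nan
    return tpr, fpr


def roc_evaluate(matrix: BafWindowMatrix, carrier_labels,
                 thresholds=None, n_bootstrap: int = 100, seed=0) -> RocResult:
    """ROC of threshold CNV calls against clone-level carrier truth.

    Positives are qc-passing (carrier cell, window) pairs of the supplied
    matrix (restrict the matrix to the event region before calling);
    negatives are non-carrier pairs.  TPR/FPR are computed per threshold,
    AUC by trapezoid over the sweep, and the uncertainty band as
    mean +/- 2 sd over ``n_bootstrap`` resamples of cells with replacement.
    """
    carrier = np.asarray(_as_seq(carrier_labels, matrix.cells), dtype=bool)
    if carrier.all() or not carrier.any():
        raise ValueError("truth labels contain a single class")
    if thresholds is None:
        thresholds = np.linspace(0.5, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)

    def curve(cell_idx):
        vals = matrix.values[cell_idx]
        qc = matrix.qc_pass[cell_idx]
        carr = carrier[cell_idx]
        if carr.all() or not carr.any():
            return None
        tprs, fprs = [], []
        for t in thresholds:
            with np.errstate(invalid="ignore"):
                calls = qc & (np.nan_to_num(vals, nan=-1.0) >= t)
            tpr, fpr = _rates(calls, qc, carr)
            tprs.append(tpr)
            fprs.append(fpr)
        tprs, fprs = np.asarray(tprs), np.asarray(fprs)
        # both rates are non-increasing in the threshold, so descending
        # threshold order traces the ROC from (0,0) to (1,1)
        f = np.concatenate([[0.0], fprs[::-1], [1.0]])
        t_ = np.concatenate([[0.0], tprs[::-1], [1.0]])
        auc = float(np.trapezoid(t_, f))
        return tprs, fprs, auc

    all_idx = np.arange(len(matrix.cells))
    tpr, fpr, auc = curve(all_idx)
    rng = as_rng(seed)
    boots_auc, boots_tpr, boots_fpr = [], [], []
    for _ in range(n_bootstrap):
        idx = rng.choice(all_idx, size=len(all_idx), replace=True)
        res = curve(idx)
        if res is None:
            continue
        boots_tpr.append(res[0])
        boots_fpr.append(res[1])
        boots_auc.append(res[2])
    boots_auc = np.asarray(boots_auc)
    band = None
    fband = None
    if len(boots_tpr):
        bt, bf = np.asarray(boots_tpr), np.asarray(boots_fpr)
        band = np.vstack([bt.mean(0) - 2 * bt.std(0, ddof=1),
                          bt.mean(0) + 2 * bt.std(0, ddof=1)])
        fband = np.vstack([bf.mean(0) - 2 * bf.std(0, ddof=1),
                           bf.mean(0) + 2 * bf.std(0, ddof=1)])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     auc_bootstrap=boots_auc, tpr_band=band, fpr_band=fband)


def _as_seq(labels, cells):
    if isinstance(labels, dict) or isinstance(labels, pd.Series):
        return [labels[c] for c in cells]
    return list(labels)
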