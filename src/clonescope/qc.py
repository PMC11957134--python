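"""Per-cell genotyping quality estimators and clonal mutation calling.

Single-cell WGA distorts genotypes in characteristic ways: allelic dropout
(ADO) silences one allele of a het site, amplification imbalance skews the
B-allele frequency, and polymerase errors create false low-BAF
heterozygous calls.  The estimators here quantify each distortion from the
cell's own read counts, using germline het SNPs as an internal truth set,
plus a linked-read (two-haplotype) precision estimator for somatic calls
and normal-cell-baseline mutation-burden correction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellQcReport",
    "HardFilterExpression",
    "estimate_ado",
    "estimate_recall_germline",
    "estimate_precision_linked",
    "estimate_false_het",
    "call_clonal_mutations",
    "apply_hard_filters",
    "estimate_burden",
]


@dataclass
class CellQcReport:
    """Per-cell quality summary; all fractions in [0,1] (NaN = undefined)."""

    cell: str
    ado_rate: float = np.nan
    recall: float = np.nan
    precision: float = np.nan
    false_het_rate: float = np.nan
    baf_mean: float = np.nan
    baf_var: float = np.nan


def estimate_ado(cell_allele_depths: pd.DataFrame,
                 het_snp_list: pd.DataFrame | None = None,
                 min_depth: int = 5) -> float:
    """Locus-level allelic dropout of one cell.

    Fraction of covered het sites (total depth >= ``min_depth``) at which
    exactly one allele is observed.  ``cell_allele_depths`` holds one row
    per het site with ref_depth/alt_depth columns; if ``het_snp_list`` is
    given, rows are first restricted to those (chrom, pos) positions.
    """
    df = cell_allele_depths
    if het_snp_list is not None:
        key = pd.MultiIndex.from_frame(het_snp_list[["chrom", "pos"]])
        df = df[pd.MultiIndex.from_frame(df[["chrom", "pos"]]).isin(key)]
    total = df["ref_depth"] + df["alt_depth"]
    covered = df[total >= min_depth]
    if len(covered) == 0:
        warnings.warn("no het site passes min_depth; ADO undefined", stacklevel=2)
        return float("nan")
    single = (covered["ref_depth"] == 0) | (covered["alt_depth"] == 0)
    return float(single.mean())


def baf_summary(cell_allele_depths: pd.DataFrame, min_depth: int = 5) -> dict:
    """Mean/variance of the BAF density over covered het sites."""
    total = cell_allele_depths["ref_depth"] + cell_allele_depths["alt_depth"]
    keep = total >= min_depth
    baf = cell_allele_depths.loc[keep, "alt_depth"] / total[keep]
    return {"baf_mean": float(baf.mean()), "baf_var": float(baf.var(ddof=1)),
            "n_sites": int(keep.sum())}


def estimate_recall_germline(cell_calls: pd.DataFrame,
                             het_snp_list: pd.DataFrame,
                             filter_pipeline: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
                             min_alt: int = 1) -> float:
    """Germline-het recall of one cell's calling pipeline.

    Fraction of het germline sites at which the variant allele survives
    the same filtering applied to somatic calls.  ``cell_calls`` is the
    cell's allele-depth (or call) table; ``filter_pipeline`` is the
    filtering stage (identity when None).
    """
    if len(het_snp_list) == 0:
        raise ValueError("empty het SNP list")
    calls = cell_calls if filter_pipeline is None else filter_pipeline(cell_calls)
    key = pd.MultiIndex.from_frame(het_snp_list[["chrom", "pos"]])
    at_het = calls[pd.MultiIndex.from_frame(calls[["chrom", "pos"]]).isin(key)]
    detected = at_het[at_het["alt_depth"] >= min_alt]
    n_detected = detected[["chrom", "pos"]].drop_duplicates().shape[0]
    return n_detected / len(het_snp_list)


def estimate_precision_linked(phased_read_pairs: pd.DataFrame,
                              min_spanning: int = 4,
                              min_reads_per_combo: int = 2) -> float:
    """Linked-read precision of candidate somatic SNVs.

    Reads spanning both a germline het SNP and a candidate somatic SNV
    should support only two haplotypes: the somatic alt allele must
    co-occur with exactly one het-SNP allele.  ``phased_read_pairs`` has
    one row per spanning read with columns ``candidate`` (sSNV id),
    ``het_allele`` (0/1) and ``snv_allele`` (0 ref / 1 alt).

    A (het allele, sSNV allele) combination counts as real only when seen
    on >= ``min_reads_per_combo`` reads, guarding against lone sequencing
    errors.  A candidate is assessable when it has >= ``min_spanning``
    reads and both het alleles observed; it is supported when its real
    alt-bearing combinations involve a single het allele.  Returns
    supported / assessable (NaN if nothing is assessable).
    """
    supported = assessable = 0
    for _, grp in phased_read_pairs.groupby("candidate"):
        if len(grp) < min_spanning:
            continue
        if grp["het_allele"].nunique() < 2:
            continue
        combos = grp.groupby(["het_allele", "snv_allele"]).size()
        real = combos[combos >= min_reads_per_combo]
        alt_partners = {h for (h, s) in real.index if s == 1}
        if not alt_partners:
            continue  # no confirmed alt reads: not assessable as a call
        assessable += 1
        if len(alt_partners) == 1:
            supported += 1
    if assessable == 0:
        warnings.warn("no assessable candidate; precision undefined", stacklevel=2)
        return float("nan")
    return supported / assessable


def estimate_false_het(cell_calls: pd.DataFrame,
                       hemizygous_region: tuple[str, int, int],
                       min_depth: int = 5, min_alt: int = 2) -> tuple[float, pd.Series]:
    """False-heterozygous rate in a region known to be hemizygous/homozygous.

    Any heterozygous call inside the region is an artifact by construction
    (e.g. chromosome 21 of a pseudodiploid line).  Returns the fraction of
    covered sites called het and the BAF values of those false calls; WGA
    polymerase errors concentrate them at low BAF.
    """
    chrom, start, end = hemizygous_region
    df = cell_calls[(cell_calls["chrom"] == chrom)
                    & (cell_calls["pos"] >= start) & (cell_calls["pos"] < end)]
    if len(df) == 0:
        raise ValueError("hemizygous region absent from calls")
    total = df["ref_depth"] + df["alt_depth"]
    covered = df[total >= min_depth]
    if len(covered) == 0:
        return float("nan"), pd.Series(dtype=float)
    tot = covered["ref_depth"] + covered["alt_depth"]
    het = (covered["alt_depth"] >= min_alt) & (covered["ref_depth"] >= min_alt)
    baf = (covered.loc[het, "alt_depth"] / tot[het]).rename("baf")
    return float(het.mean()), baf.reset_index(drop=True)


def call_clonal_mutations(cell_calls: Mapping[str, Iterable],
                          min_concordant: int = 2,
                          bulk_germline: Iterable = (),
                          normal_cell_calls: Mapping[str, Iterable] | None = None) -> set:
    """Clone-level consensus mutation calling.

    A variant is retained iff it is called identically in at least
    ``min_concordant`` cells of the clone, is absent from the bulk
    germline call set, and is absent from every normal single cell.
    ``cell_calls`` maps cell name -> iterable of variant keys.
    """
    if len(cell_calls) < 2:
        raise ValueError("clonal calling requires >= 2 cells per clone")
    if min_concordant < 1:
        raise ValueError("min_concordant must be >= 1")
    counts: dict = {}
    for calls in cell_calls.values():
        for v in set(calls):
            counts[v] = counts.get(v, 0) + 1
    keep = {v for v, c in counts.items() if c >= min_concordant}
    keep -= set(bulk_germline)
    if normal_cell_calls:
        for calls in normal_cell_calls.values():
            keep -= set(calls)
    return keep


_CLAUSE_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*([<>]=?)\s*(-?\d+(?:\.\d+)?)\s*$")
_COMPARATORS = {
    "<": np.less, ">": np.greater, "<=": np.less_equal, ">=": np.greater_equal,
}


@dataclass(frozen=True)
class HardFilterExpression:
    """GATK-style OR-of-clauses hard filter, e.g. ``"QD < 2.0 || FS > 60.0"``.

    A record is removed iff any clause is true.  Clauses referencing a
    metric a record does not expose are skipped for that record (logged).
    """

    clauses: tuple  # ((metric, comparator, threshold), ...)

    @classmethod
    def parse(cls, expression: str) -> "HardFilterExpression":
        clauses = []
        for i, raw in enumerate(expression.split("||")):
            m = _CLAUSE_RE.match(raw)
            if not m:
                raise ValueError(f"unparsable clause #{i + 1}: {raw!r}")
            metric, op, thr = m.groups()
            clauses.append((metric, op, float(thr)))
        return cls(tuple(clauses))

    def __str__(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}" if x != int(x) else f"{x:.1f}"
        return " || ".join(f"{m} {op} {fmt(t)}" for m, op, t in self.clauses)


#: The standard germline-quality hard filter used for single-cell exome calls.
DEFAULT_HARD_FILTER = HardFilterExpression.parse(
    "QD < 2.0 || FS > 60.0 || MQ < 40.0 || HaplotypeScore > 13.0 || "
    "MQRankSum < -12.5 || ReadPosRankSum < -8.0")


def apply_hard_filters(records: pd.DataFrame,
                       expression: HardFilterExpression | str = DEFAULT_HARD_FILTER,
                       ) -> pd.DataFrame:
    """Drop records failing any clause of an OR hard-filter expression.

    Clause metrics absent from ``records`` are skipped with a warning
    (filter not applied); NaN metric values do not trigger a clause.
    """
    if isinstance(expression, str):
        expression = HardFilterExpression.parse(expression)
    fail = np.zeros(len(records), dtype=bool)
    for metric, op, thr in expression.clauses:
        if metric not in records.columns:
            warnings.warn(f"metric {metric!r} missing; clause skipped", stacklevel=2)
            continue
        vals = records[metric].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            hit = _COMPARATORS[op](vals, thr)
        fail |= np.nan_to_num(hit, nan=0.0).astype(bool)
    return records[~fail]


def estimate_burden(cell_call_rates: Mapping[str, float] | pd.Series,
                    normal_cell_call_rates: Sequence[float] | pd.Series,
                    callable_mb: float = 2800.0) -> pd.DataFrame:
    """Normal-baseline-corrected per-cell mutation burden.

    Subtracts the mean call count of normal cells (amplification
    artifacts, somatic mosaicism, miscalls) from each tumor cell's raw
    count.  Returns per-cell corrected counts and per-megabase rates
    (callable genome size configurable, default 2,800 Mb).  Negative
    corrected burdens are reported as-is with a warning.
    """
    normals = np.asarray(list(normal_cell_call_rates), dtype=float)
    if normals.size == 0:
        raise ValueError("need at least one normal cell")
    baseline = normals.mean()
    s = pd.Series(dict(cell_call_rates)) if not isinstance(cell_call_rates, pd.Series) \
        else cell_call_rates.astype(float)
    corrected = s - baseline
    if (corrected < 0).any():
        warnings.warn("negative corrected burden (possible over-correction)",
                      stacklevel=2)
    return pd.DataFrame({
        "raw": s,
        "corrected": corrected,
        "corrected_per_mb": corrected / callable_mb,
    })
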