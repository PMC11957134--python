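"""Error-corrected sequencing: UMI-family consensus and tumor/normal somatic tests.

Reads sharing a unique molecular identifier (UMI) derive from one original
molecule; a per-position majority consensus over the family removes most
polymerase and sequencing errors.  Consensus pileups from a tumor and a
matched normal are then compared site-by-site with a one-sided Fisher's
exact test, with germline-contamination and strand-bias filters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConsensusParams",
    "SomaticFilterParams",
    "ConsensusResult",
    "call_consensus",
    "consensus_set",
    "call_somatic",
]


@dataclass(frozen=True)
class ConsensusParams:
    """Family-consensus thresholds.

    minmem
        Minimum number of reads per UMI family; smaller families are
        rejected outright.
    base_cutoff
        Minimum fraction of family reads agreeing at a position for the
        base to be emitted; below it an 'N' is written.  Ties at exactly
        the cutoff are emitted (>=).
    n_cutoff
        Minimum fraction of non-'N' positions for the consensus to be
        kept; a consensus with more than ``1 - n_cutoff`` ambiguous
        positions is discarded.
    """

    minmem: int = 3
    base_cutoff: float = 0.8
    n_cutoff: float = 0.7

    def __post_init__(self):
        if self.minmem < 1:
            raise ValueError("minmem must be >= 1")
        if not (0.5 < self.base_cutoff <= 1.0):
            raise ValueError("base_cutoff must be in (0.5, 1]")
        if not (0.0 < self.n_cutoff <= 1.0):
            raise ValueError("n_cutoff must be in (0, 1]")


@dataclass(frozen=True)
class SomaticFilterParams:
    """Somatic-call filters applied after the Fisher test."""

    p_threshold: float = 1e-4
    max_normal_alt_reads: int = 5  # exclusive: normal alt reads must be < 5
    max_strand_fraction: float = 0.9

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0.0 < self.max_strand_fraction <= 1.0):
            raise ValueError("max_strand_fraction must be in (0,1]")


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str | None
    reason: str = "ok"

    @property
    def accepted(self) -> bool:
        return self.sequence is not None


def call_consensus(family, params: ConsensusParams = ConsensusParams()) -> ConsensusResult:
    """Collapse one UMI family to a consensus sequence, or reject it.

    ``family`` is any object with a ``reads`` attribute (list of equal-length
    strings aligned to common coordinates), or a bare list of strings.
    """
    reads = getattr(family, "reads", family)
    if len(reads) == 0:
        return ConsensusResult(None, "empty_family")
    if len(reads) < params.minmem:
        return ConsensusResult(None, "below_minmem")
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError("family reads must share a common aligned length")
    n = len(reads)
    out = []
    for col in zip(*reads):
        base, count = Counter(col).most_common(1)[0]
        out.append(base if count / n >= params.base_cutoff else "N")
    seq = "".join(out)
    n_frac = seq.count("N") / len(seq)
    if n_frac > (1.0 - params.n_cutoff):
        return ConsensusResult(None, "too_many_N")
    return ConsensusResult(seq)


def consensus_set(families, params: ConsensusParams = ConsensusParams()) -> pd.DataFrame:
    """Consensus-call every family; one row per family with outcome."""
    rows = []
    for fam in families:
        res = call_consensus(fam, params)
        rows.append({
            "umi": getattr(fam, "umi", None),
            "size": len(getattr(fam, "reads", fam)),
            "consensus": res.sequence,
            "accepted": res.accepted,
            "reason": res.reason,
        })
    return pd.DataFrame(rows)


_REQUIRED = ["chrom", "pos", "ref_depth", "alt_depth"]


def call_somatic(tumor_pileup: pd.DataFrame, normal_pileup: pd.DataFrame,
                 params: SomaticFilterParams = SomaticFilterParams()) -> pd.DataFrame:
    """Site-wise tumor-vs-normal somatic variant test.

    Pileups are DataFrames with columns chrom, pos, ref_depth, alt_depth and
    (tumor only, optional) alt_fwd / alt_rev strand counts.  Each shared
    site is tested with a one-sided Fisher's exact test for alt-allele
    enrichment in the tumor; a site is reported somatic iff

    * p < ``p_threshold``,
    * the normal carries fewer than ``max_normal_alt_reads`` alt reads, and
    * no more than ``max_strand_fraction`` of tumor alt reads sit on one
      strand (when strand counts are available).

    Returns one row per shared site with the p-value and per-filter flags;
    zero-depth sites are skipped.
    """
    for df, name in ((tumor_pileup, "tumor"), (normal_pileup, "normal")):
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"{name} pileup lacks columns {missing}")
    merged = tumor_pileup.merge(normal_pileup, on=["chrom", "pos"],
                                suffixes=("_t", "_n"))
    rows = []
    for r in merged.itertuples(index=False):
        t_alt, t_ref = int(r.alt_depth_t), int(r.ref_depth_t)
        n_alt, n_ref = int(r.alt_depth_n), int(r.ref_depth_n)
        if t_alt + t_ref == 0 or n_alt + n_ref == 0:
            continue  # zero-depth site: uninformative
        _, p = stats.fisher_exact([[t_alt, t_ref], [n_alt, n_ref]],
                                  alternative="greater")
        strand_frac = np.nan
        if hasattr(r, "alt_fwd") and hasattr(r, "alt_rev"):
            fwd, rev = int(r.alt_fwd), int(r.alt_rev)
            if fwd + rev > 0:
                strand_frac = max(fwd, rev) / (fwd + rev)
        pass_p = p < params.p_threshold
        pass_normal = n_alt < params.max_normal_alt_reads
        pass_strand = (np.isnan(strand_frac)
                       or strand_frac <= params.max_strand_fraction)
        rows.append({
            "chrom": r.chrom, "pos": r.pos,
            "tumor_alt": t_alt, "tumor_ref": t_ref,
            "normal_alt": n_alt, "normal_ref": n_ref,
            "somatic_p": p, "strand_frac": strand_frac,
            "pass_p": pass_p, "pass_normal": pass_normal,
            "pass_strand": bool(pass_strand),
            "somatic": bool(pass_p and pass_normal and pass_strand),
        })
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "tumor_alt", "tumor_ref", "normal_alt", "normal_ref",
        "somatic_p", "strand_frac", "pass_p", "pass_normal", "pass_strand",
        "somatic"])
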