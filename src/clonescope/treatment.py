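"""Ex vivo drug-response clustering and emergent-clone detection.

Mutation variant-allele-frequency (VAF) profiles across drug/dose/replicate
conditions are clustered hierarchically on both axes to reveal clone groups
with shared treatment response; post-treatment clones whose defining
variants and CNVs were all undetected pre-treatment are reported as
emergent, with a rule-of-three upper bound on their pre-treatment
frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "TreatmentVafMatrix",
    "cluster_vaf_matrix",
    "EmergentCloneReport",
    "detect_emergent_clones",
]

#: VAF detection limit of the error-corrected assay.
DEFAULT_DETECTION_LIMIT = 0.005


@dataclass
class TreatmentVafMatrix:
    """Mutations x treatment-condition VAF matrix.

    Column labels are (drug, dose, replicate) tuples or strings; VAFs lie
    in [0,1] with missing values imputed as 0 (below detection).
    """

    values: pd.DataFrame
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        v = np.nan_to_num(v, nan=0.0)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("VAFs must lie in [0,1]")
        self.values = pd.DataFrame(v, index=self.values.index,
                                   columns=self.values.columns)


def _axis_linkage(X: np.ndarray, distance: str, linkage: str) -> np.ndarray:
    if distance == "correlation":
        # rows with zero variance would make correlation undefined
        sd = X.std(axis=1)
        X = X.copy()
        X[sd == 0] += np.random.default_rng(0).normal(0, 1e-12, X.shape[1])
        d = pdist(X, metric="correlation")
    else:
        d = pdist(X, metric=distance)
    return hierarchy.linkage(d, method=linkage)


def cluster_vaf_matrix(matrix: TreatmentVafMatrix | pd.DataFrame,
                       linkage: str = "average",
                       distance: str = "correlation",
                       n_row_clusters: int | None = None,
                       cut_height: float | None = None) -> dict:
    """Hierarchical clustering of mutations (rows) and conditions (columns).

    Returns the row and column linkage matrices plus flat row clusters
    (by ``n_row_clusters`` or ``cut_height``; default 2 clusters).
    Deterministic given inputs; a constant matrix is flagged degenerate.
    """
    df = matrix.values if isinstance(matrix, TreatmentVafMatrix) else matrix
    df = df.fillna(0.0)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    X = df.to_numpy(dtype=float)
    degenerate = bool(np.allclose(X, X.flat[0]))
    if degenerate:
        warnings.warn("constant matrix; clustering degenerate", stacklevel=2)
    row_link = _axis_linkage(X, distance, linkage)
    col_link = _axis_linkage(X.T, distance, linkage)
    if cut_height is not None:
        flat = hierarchy.fcluster(row_link, t=cut_height, criterion="distance")
    else:
        flat = hierarchy.fcluster(row_link, t=n_row_clusters or 2,
                                  criterion="maxclust")
    return {"row_linkage": row_link, "col_linkage": col_link,
            "row_clusters": pd.Series(flat, index=df.index),
            "row_order": list(df.index[hierarchy.leaves_list(row_link)]),
            "col_order": list(df.columns[hierarchy.leaves_list(col_link)]),
            "degenerate": degenerate}


@dataclass
class EmergentCloneReport:
    clone: str
    defining_variants: list
    defining_cnvs: list = field(default_factory=list)
    emergent: bool = False
    detected_pre: list = field(default_factory=list)
    pre_frequency_upper_bound: float | None = None
    post_cell_fraction: float | None = None


def rule_of_three(n: int) -> float:
    """95% upper bound on a proportion observed 0 times in n samples."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 / n


def detect_emergent_clones(pre_calls: pd.DataFrame,
                           post_tree_clones: dict,
                           detection_limit: float = DEFAULT_DETECTION_LIMIT,
                           pre_cell_count: int | None = None,
                           pre_cnvs: set | None = None,
                           post_cell_fractions: dict | None = None) -> list:
    """Flag post-treatment clones undetected before treatment.

    ``pre_calls`` has columns variant, vaf (pre-treatment bulk VAFs);
    ``post_tree_clones`` maps clone id -> dict with ``variants`` (list)
    and optional ``cnvs`` (list).  A clone is emergent iff none of its
    defining variants reach ``detection_limit`` pre-treatment and none of
    its defining CNVs are in ``pre_cnvs``.  With ``pre_cell_count`` n,
    emergent clones get the rule-of-three 3/n upper bound on their
    undetected pre-treatment frequency.
    """
    vafs = pre_calls.set_index("variant")["vaf"] if len(pre_calls) else pd.Series(dtype=float)
    pre_cnvs = set(pre_cnvs or ())
    reports = []
    for clone, spec in post_tree_clones.items():
        variants = list(spec.get("variants", ()))
        cnvs = list(spec.get("cnvs", ()))
        if not variants and not cnvs:
            raise ValueError(f"clone {clone!r} has no defining variants or CNVs")
        detected = [v for v in variants
                    if v in vafs.index and vafs[v] >= detection_limit]
        detected += [c for c in cnvs if c in pre_cnvs]
        emergent = len(detected) == 0
        rep = EmergentCloneReport(
            clone=clone, defining_variants=variants, defining_cnvs=cnvs,
            emergent=emergent, detected_pre=detected,
            pre_frequency_upper_bound=(rule_of_three(pre_cell_count)
                                       if emergent and pre_cell_count else None),
            post_cell_fraction=(post_cell_fractions or {}).get(clone))
        reports.append(rep)
    return reports
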