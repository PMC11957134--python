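"""SBS96 trinucleotide mutational-signature construction, fitting, extraction.

Single-base substitutions are classified into the canonical 96 categories
(pyrimidine-centered trinucleotide contexts; purine-reference variants are
reverse-complemented).  Exposures to a reference catalogue are fitted per
sample by non-negative least squares; small-scale de novo extraction uses
multiplicative-update NMF with the KL (Poisson-appropriate) objective, and
candidate signatures are matched to the catalogue by cosine similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .simulate import as_rng

__all__ = [
    "SBS96_CATEGORIES",
    "sbs96_matrix",
    "fit_signatures",
    "extract_de_novo",
    "early_late_contrast",
    "cosine_similarity",
    "synthetic_reference_catalogue",
]

_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical COSMIC-style ordering: substitution class major, then 5' base,
#: then 3' base, each in A/C/G/T order.
SBS96_CATEGORIES = [f"{f}[{sub}]{t}"
                    for sub in _SUBS for f in _BASES for t in _BASES]
_CAT_INDEX = {c: i for i, c in enumerate(SBS96_CATEGORIES)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_sbs96(ref: str, alt: str, context: str) -> str | None:
    """Map a substitution with trinucleotide context to its SBS96 category.

    ``context`` is the reference trinucleotide centered on the variant.
    Purine references are reverse-complemented into the pyrimidine-centered
    convention.  Returns None (caller logs/skips) for ambiguous contexts.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or any(b not in _BASES for b in context) \
            or ref not in _BASES or alt not in _BASES or ref == alt:
        return None
    if context[1] != ref:
        return None
    if ref in "AG":
        context = _revcomp(context)
        ref = context[1]
        alt = alt.translate(_COMPLEMENT)
    cat = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return cat if cat in _CAT_INDEX else None


def sbs96_matrix(variants: pd.DataFrame, reference_contexts=None,
                 sample_col: str = "sample") -> pd.DataFrame:
    """Accumulate variants into a 96 x samples count matrix.

    ``variants`` needs columns ref, alt and either ``context`` (the
    reference trinucleotide) or chrom/pos with ``reference_contexts``
    being a callable ``(chrom, pos) -> trinucleotide`` (e.g. wrapping a
    FASTA).  Variants with ambiguous contexts (N, mismatching center) are
    skipped with a warning.  Column sums equal the per-sample counts of
    classifiable SNVs.
    """
    df = variants.copy()
    if "context" not in df.columns:
        if reference_contexts is None:
            raise ValueError("need a context column or a reference_contexts lookup")
        df["context"] = [reference_contexts(c, p)
                         for c, p in zip(df["chrom"], df["pos"])]
    if sample_col not in df.columns:
        df[sample_col] = "sample"
    samples = list(pd.unique(df[sample_col]))
    M = np.zeros((96, len(samples)), dtype=int)
    sidx = {s: j for j, s in enumerate(samples)}
    skipped = 0
    for r in df.itertuples(index=False):
        cat = classify_sbs96(r.ref, r.alt, r.context)
        if cat is None:
            skipped += 1
            continue
        M[_CAT_INDEX[cat], sidx[getattr(r, sample_col)]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} variants with ambiguous context",
                      stacklevel=2)
    return pd.DataFrame(M, index=SBS96_CATEGORIES, columns=samples)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def fit_signatures(matrix: pd.DataFrame, reference_signatures: pd.DataFrame,
                   normalize: bool = False) -> dict:
    """Per-sample NNLS fit of context counts to a reference catalogue.

    ``reference_signatures`` is 96 x signatures with columns summing to 1.
    Returns a dict with ``exposures`` (signatures x samples),
    ``residual`` (per-sample NNLS residual norm) and ``cosine``
    (reconstruction cosine similarity per sample).  Zero-count samples get
    zero exposures and are flagged NaN cosine.
    """
    R = reference_signatures.reindex(matrix.index).to_numpy(dtype=float)
    if not np.allclose(R.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")
    expo = np.zeros((R.shape[1], matrix.shape[1]))
    resid = np.zeros(matrix.shape[1])
    cos = np.zeros(matrix.shape[1])
    for j, sample in enumerate(matrix.columns):
        y = matrix[sample].to_numpy(dtype=float)
        if y.sum() == 0:
            warnings.warn(f"zero-count sample {sample!r}", stacklevel=2)
            cos[j] = np.nan
            continue
        w, rnorm = nnls(R, y)
        expo[:, j] = w
        resid[j] = rnorm
        cos[j] = cosine_similarity(R @ w, y)
    exposures = pd.DataFrame(expo, index=reference_signatures.columns,
                             columns=matrix.columns)
    if normalize:
        tot = exposures.sum(axis=0)
        exposures = exposures.divide(tot.replace(0, np.nan), axis=1)
    return {"exposures": exposures,
            "residual": pd.Series(resid, index=matrix.columns),
            "cosine": pd.Series(cos, index=matrix.columns)}


def extract_de_novo(matrix: pd.DataFrame, k: int, n_restarts: int = 10,
                    seed=0, reference_signatures: pd.DataFrame | None = None,
                    max_iter: int = 2000) -> dict:
    """De novo signature extraction by KL-divergence NMF, best of restarts.

    Factorizes the 96 x samples count matrix as W H with k signatures;
    signatures (columns of W) are L1-normalized, exposures rescaled to
    compensate.  When a reference catalogue is given, each de novo
    signature is matched to its nearest reference by cosine similarity.
    """
    if k >= 96:
        raise ValueError("k must be < 96")
    if k >= matrix.shape[1]:
        warnings.warn("k >= number of samples: extraction likely overfit",
                      stacklevel=2)
    rng = as_rng(seed)
    X = matrix.to_numpy(dtype=float)
    best = None
    for r in range(n_restarts):
        model = NMF(n_components=k, init="random", solver="mu",
                    beta_loss="kullback-leibler", max_iter=max_iter,
                    random_state=int(rng.integers(0, 2**31 - 1)), tol=1e-6)
        W = model.fit_transform(X)
        H = model.components_
        err = model.reconstruction_err_
        if best is None or err < best[0]:
            best = (err, W, H)
    _, W, H = best
    norms = W.sum(axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    names = [f"SBS96{chr(ord('A') + i)}" for i in range(k)]
    sigs = pd.DataFrame(W, index=matrix.index, columns=names)
    expo = pd.DataFrame(H, index=names, columns=matrix.columns)
    out = {"signatures": sigs, "exposures": expo, "reconstruction_err": best[0]}
    if reference_signatures is not None:
        matches = {}
        for name in names:
            sims = {ref: cosine_similarity(sigs[name], reference_signatures[ref])
                    for ref in reference_signatures.columns}
            top = max(sims, key=sims.get)
            matches[name] = {"best_match": top, "cosine": sims[top]}
        out["reference_match"] = pd.DataFrame(matches).T
    return out


def early_late_contrast(shared_variants: pd.DataFrame,
                        private_variants: pd.DataFrame,
                        fdr: float = 0.05) -> dict:
    """Contrast context spectra of shared (early) vs private (late) variants.

    Builds one SBS96 profile per class and runs a per-category
    two-proportion z-test with Benjamini-Hochberg correction.  Classes
    with a single variant are flagged underpowered.
    """
    if len(shared_variants) == 0 or len(private_variants) == 0:
        raise ValueError("both variant classes must be non-empty")
    m_shared = sbs96_matrix(shared_variants.assign(sample="shared"))
    m_private = sbs96_matrix(private_variants.assign(sample="private"))
    counts = pd.DataFrame({"shared": m_shared.iloc[:, 0],
                           "private": m_private.iloc[:, 0]})
    n_s, n_p = counts["shared"].sum(), counts["private"].sum()
    underpowered = n_s < 2 or n_p < 2
    pvals = np.ones(96)
    for i in range(96):
        cs, cp = counts["shared"].iloc[i], counts["private"].iloc[i]
        if cs + cp == 0:
            continue
        _, p = proportions_ztest([cs, cp], [n_s, n_p])
        pvals[i] = p if np.isfinite(p) else 1.0
    rej, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    table = counts.copy()
    table["p"] = pvals
    table["q"] = qvals
    table["significant"] = rej
    if underpowered:
        warnings.warn("a class has < 2 classifiable variants; contrast underpowered",
                      stacklevel=2)
    return {"matrix": counts, "tests": table, "underpowered": underpowered}


def synthetic_reference_catalogue(seed=0) -> pd.DataFrame:
    """Small synthetic reference catalogue of three SBS96 signatures.

    Constructed stand-ins with the qualitative shapes relevant here:
    ``FLAT_CLOCK`` (broad, clock-like), ``CPG_CT`` (C>T concentrated at
    NpCpG contexts) and ``APOBEC_TPC`` (C>T/C>G at TpC motifs).  Columns
    are L1-normalized.  Synthetic: not measured catalogue entries.
    """
    rng = as_rng(seed)
    flat = rng.gamma(5.0, 1.0, size=96)
    cpg = np.full(96, 0.05)
    apobec = np.full(96, 0.02)
    for i, cat in enumerate(SBS96_CATEGORIES):
        five, sub, three = cat[0], cat[2:5], cat[6]
        if sub == "C>T" and three == "G":
            cpg[i] = 10.0
        if sub in ("C>T", "C>G") and five == "T":
            apobec[i] = 12.0
    cat = pd.DataFrame({"FLAT_CLOCK": flat, "CPG_CT": cpg, "APOBEC_TPC": apobec},
                       index=SBS96_CATEGORIES)
    return cat / cat.sum(axis=0)
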