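"""Generative models for single-cell whole-genome-amplification experiments.

This module simulates the ground truth that the downstream estimators are
designed to recover: a clone tree over cells with Poisson mutation
accumulation proportional to culture time, allele read counts distorted by
whole-genome-amplification (WGA) chemistry (allelic dropout, beta-binomial
amplification imbalance, polymerase errors), hemizygous-deletion BAF shifts,
UMI read families, and heritable (Brownian-motion-on-tree) surface-marker
phenotypes.

All randomness flows through ``numpy.random.Generator``; every public
function accepts either a seed or a Generator, and identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "WgaProfile",
    "PTA_PROFILE",
    "MDA_PROFILE",
    "CloneTruth",
    "CnvEvent",
    "UmiFamily",
    "UmiFamilySet",
    "simulate_clone_tree",
    "simulate_wga_readcounts",
    "inject_cnv",
    "simulate_umi_families",
    "simulate_phenotypes",
    "genotype_calls_from_depths",
    "simulate_het_snp_positions",
    "invitro_benchmark_design",
]


def as_rng(seed) -> np.random.Generator:
    """Coerce a seed or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class WgaProfile:
    """Statistical profile of a single-cell WGA chemistry.

    Parameters
    ----------
    ado_rate : float
        Locus-level allelic dropout: expected fraction of covered
        heterozygous sites at which only one allele is observed.
        PTA chemistry runs near 0.057, MDA near 0.164.
    amp_error_rate : float
        Per-read probability that a base at the site is mis-copied to the
        other allele during amplification (polymerase error background).
    imbalance_dispersion : float
        Overdispersion of the allele fraction at balanced het sites; the
        fraction is drawn Beta(c, c) with ``c = 1 / imbalance_dispersion``,
        so 0+ means tight 0.5 BAF and larger values widen the density.
    mean_depth : float
        Mean sequencing depth per site (Poisson).
    """

    ado_rate: float = 0.057
    amp_error_rate: float = 1e-3
    imbalance_dispersion: float = 0.08
    mean_depth: float = 30.0

    def __post_init__(self):
        if not (0.0 <= self.ado_rate < 1.0):
            raise ValueError(f"ado_rate must be in [0,1): {self.ado_rate}")
        if not (0.0 <= self.amp_error_rate < 1.0):
            raise ValueError("amp_error_rate must be in [0,1)")
        if self.imbalance_dispersion < 0:
            raise ValueError("imbalance_dispersion must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def per_allele_dropout(self) -> float:
        """Per-allele dropout probability q.

        Each allele of a het site fails to amplify independently with
        probability q; conditioned on the site retaining coverage, the
        fraction showing a single allele is 2q(1-q)/(1-q^2) = 2q/(1+q),
        which is the locus-level ``ado_rate``.  Inverting gives
        q = a / (2 - a).
        """
        a = self.ado_rate
        return a / (2.0 - a)


#: PTA-like chemistry: low dropout, mild amplification imbalance.
PTA_PROFILE = WgaProfile(ado_rate=0.057, amp_error_rate=1e-3,
                         imbalance_dispersion=0.08, mean_depth=30.0)
#: MDA-like chemistry: high dropout and strong allelic imbalance.
MDA_PROFILE = WgaProfile(ado_rate=0.164, amp_error_rate=2e-3,
                         imbalance_dispersion=0.45, mean_depth=30.0)


@dataclass(frozen=True)
class CnvEvent:
    """A clone-restricted hemizygous deletion; coordinates 0-based half-open."""

    clone: int
    chrom: str
    start: int
    end: int
    lost_haplotype: str = "A"

    def __post_init__(self):
        if self.end < self.start or self.start < 0:
            raise ValueError("CNV interval must be half-open with non-negative length")


@dataclass
class CloneTruth:
    """Ground truth for a simulated in vitro clone expansion.

    Attributes
    ----------
    tree : dendropy.Tree
        Rooted cell tree; edge lengths in days of culture.  Internal node
        labels are unique; each edge carries ``n_mutations`` and the list of
        mutation ids assigned to it in ``mutation_assignments``.
    clone_of_cell : dict
        cell name -> clone index.
    mutation_assignments : dict
        mutation id -> head-node label of the edge carrying it.
    culture_time_of_cell : dict
        cell name -> total days from experiment start to sampling.
    cnv_events : list of CnvEvent
    """

    tree: dendropy.Tree
    clone_of_cell: dict
    mutation_assignments: dict
    culture_time_of_cell: dict
    cnv_events: list = field(default_factory=list)

    @property
    def cells(self) -> list:
        return sorted(self.clone_of_cell)

    def mutation_tree(self) -> dendropy.Tree:
        """Copy of the truth tree with edge lengths in mutation counts."""
        t = self.tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.head_node is t.seed_node and edge.length is None:
                continue
            label = edge.head_node.label or edge.head_node.taxon.label
            edge.length = float(self._edge_counts.get(label, 0))
        return t

    # populated by simulate_clone_tree
    _edge_counts: dict = field(default_factory=dict, repr=False)


def invitro_benchmark_design() -> dict:
    """Sampling design of a 16-cell serial clone-expansion benchmark.

    Two parental cells sampled early plus two cells from each of seven
    subclones sampled at weekly intervals over several weeks of culture.
    Returns keyword arguments for :func:`simulate_clone_tree`.
    """
    return dict(
        n_cells=16,
        n_clones=8,
        sampling_schedule=[10.0, 25.0, 32.0, 39.0, 46.0, 53.0, 60.0, 67.0],
        cells_per_clone=[2] * 8,
    )


def simulate_clone_tree(
    n_cells: int,
    n_clones: int,
    mutations_per_day: float,
    sampling_schedule: Sequence[float] | None = None,
    seed=0,
    cells_per_clone: Sequence[int] | None = None,
    within_clone_days: float = 2.0,
) -> tuple[CloneTruth, pd.DataFrame]:
    """Simulate a clone tree and the truth genotype matrix of sampled cells.

    Clones arise by serial subcloning from a single founder lineage: the
    clone with the longest culture time forms the backbone and every other
    clone branches off it at a random time before its own sampling day.
    Mutations accumulate on every branch as Poisson(rate x branch days);
    the truth genotype of a cell is the union of the mutations on its
    root-to-tip path, so the matrix is perfectly tree-compatible.

    Parameters
    ----------
    n_cells, n_clones : int
        Number of sampled cells and clones; ``n_clones <= n_cells``.
    mutations_per_day : float
        Poisson mutation accumulation rate (observed-mutation scale).
    sampling_schedule : sequence of float, optional
        Culture time (days) at which each clone is sampled; defaults to
        evenly spaced times between 20 and 60 days.
    cells_per_clone : sequence of int, optional
        Explicit allocation summing to ``n_cells``; default round-robin.
    within_clone_days : float
        Days of within-clone expansion before sampling; cells of a clone
        diverge from each other this long before their sampling day, so
        they share every clone-private mutation older than that.

    Returns
    -------
    (CloneTruth, DataFrame)
        Truth object and the cells x mutations binary genotype matrix.
    """
    rng = as_rng(seed)
    if mutations_per_day <= 0:
        raise ValueError(f"mutations_per_day must be positive, got {mutations_per_day}")
    if n_clones > n_cells:
        raise ValueError("n_clones cannot exceed n_cells")
    if n_clones < 1:
        raise ValueError("need at least one clone")
    if sampling_schedule is None:
        sampling_schedule = np.linspace(20.0, 60.0, n_clones)
    times = np.asarray(sampling_schedule, dtype=float)
    if len(times) != n_clones:
        raise ValueError("sampling_schedule must give one culture duration per clone")
    if np.any(times < 0):
        raise ValueError("culture times must be >= 0")
    if cells_per_clone is None:
        base = n_cells // n_clones
        cells_per_clone = [base + (1 if i < n_cells % n_clones else 0)
                           for i in range(n_clones)]
    if sum(cells_per_clone) != n_cells:
        raise ValueError("cells_per_clone must sum to n_cells")

    # Backbone = clone with the longest culture; others attach at a random
    # fraction of their own culture span (all before their sampling day).
    order = list(np.argsort(-times, kind="stable"))
    backbone = order[0]
    attach = {}
    for c in order[1:]:
        attach[c] = float(rng.uniform(0.05, 0.6) * times[c])
    events = sorted(attach.items(), key=lambda kv: kv[1])  # (clone, split time)

    def clone_subtree(c: int, start: float) -> str:
        names = [f"cell_{c}_{i}" for i in range(cells_per_clone[c])]
        tip_len = min(within_clone_days, max(times[c] - start, 0.0))
        if cells_per_clone[c] == 1:
            return f"{names[0]}:{times[c] - start:.6f}"
        stem = max(times[c] - start - tip_len, 0.0)
        inner = ",".join(f"{n}:{tip_len:.6f}" for n in names)
        return f"({inner})clone{c}anc:{stem:.6f}"

    # Nest backbone splits from tip inward.
    newick = clone_subtree(backbone, events[-1][1] if events else 0.0)
    for i, (c, s) in enumerate(reversed(events)):
        upstream = events[-i - 2][1] if i + 1 < len(events) else 0.0
        newick = (f"({clone_subtree(c, s)},{newick})split{c}:{s - upstream:.6f}")
    newick = f"({newick})root;"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    # unique labels for unlabeled internals
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.taxon is None and not nd.label:
            nd.label = f"node{k}"
            k += 1

    clone_of_cell, culture_time = {}, {}
    for c in range(n_clones):
        for i in range(cells_per_clone[c]):
            name = f"cell_{c}_{i}"
            clone_of_cell[name] = c
            culture_time[name] = float(times[c])

    # Poisson mutations per edge.
    mutation_assignments, edge_counts = {}, {}
    mut_id = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        label = edge.head_node.label or edge.head_node.taxon.label
        m = int(rng.poisson(mutations_per_day * edge.length))
        edge_counts[label] = m
        for _ in range(m):
            mutation_assignments[f"m{mut_id}"] = label
            mut_id += 1

    truth = CloneTruth(tree=tree, clone_of_cell=clone_of_cell,
                       mutation_assignments=mutation_assignments,
                       culture_time_of_cell=culture_time)
    truth._edge_counts = edge_counts

    # genotype = union of mutations along root-to-tip path
    muts_by_edge = {}
    for mid, label in mutation_assignments.items():
        muts_by_edge.setdefault(label, []).append(mid)
    all_muts = [f"m{i}" for i in range(mut_id)]
    col_index = {m: j for j, m in enumerate(all_muts)}
    cells = sorted(clone_of_cell)
    G = np.zeros((len(cells), mut_id), dtype=np.int8)
    row_index = {c: i for i, c in enumerate(cells)}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        node = leaf
        while node is not None:
            label = node.label or (node.taxon.label if node.taxon else None)
            for mid in muts_by_edge.get(label, ()):
                G[row_index[name], col_index[mid]] = 1
            node = node.parent_node
    genotypes = pd.DataFrame(G, index=cells, columns=all_muts)
    return truth, genotypes


def simulate_het_snp_positions(n_sites: int, chrom: str = "chr13",
                               start: int = 0, end: int | None = None,
                               seed=0) -> pd.DataFrame:
    """Uniformly placed germline het-SNP positions (0-based, unique)."""
    rng = as_rng(seed)
    if end is None:
        end = start + int(n_sites * 1200)  # ~1 het SNP / 1.2 kb, human-like
    pos = np.sort(rng.choice(np.arange(start, end), size=n_sites, replace=False))
    return pd.DataFrame({"chrom": chrom, "pos": pos})


def _simulate_depth_arrays(geno: np.ndarray, profile: WgaProfile,
                           rng: np.random.Generator):
    """Vectorized WGA read-count simulation for a genotype-code array.

    geno codes: 0 hom-ref, 1 het, 2 hom-alt.  Returns (ref_depth, alt_depth)
    int arrays of the same shape.
    """
    shape = geno.shape
    depth = rng.poisson(profile.mean_depth, size=shape)
    q = profile.per_allele_dropout
    drop_ref = rng.random(shape) < q
    drop_alt = rng.random(shape) < q
    c = np.inf if profile.imbalance_dispersion == 0 else 1.0 / profile.imbalance_dispersion
    if np.isinf(c):
        p_alt = np.full(shape, 0.5)
    else:
        p_alt = rng.beta(c, c, size=shape)

    ref = np.zeros(shape, dtype=np.int64)
    alt = np.zeros(shape, dtype=np.int64)

    het = geno == 1
    both = het & ~drop_ref & ~drop_alt
    only_ref = het & ~drop_ref & drop_alt
    only_alt = het & drop_ref & ~drop_alt
    # both dropped -> no template -> zero coverage
    alt[both] = rng.binomial(depth[both], p_alt[both])
    ref[both] = depth[both] - alt[both]
    ref[only_ref] = depth[only_ref]
    alt[only_alt] = depth[only_alt]
    hom_ref = geno == 0
    ref[hom_ref] = depth[hom_ref]
    hom_alt = geno == 2
    alt[hom_alt] = depth[hom_alt]

    # amplification/sequencing errors flip reads to the other allele
    e = profile.amp_error_rate
    if e > 0:
        err_to_alt = rng.binomial(ref, e)
        err_to_ref = rng.binomial(alt, e)
        ref = ref - err_to_alt + err_to_ref
        alt = alt - err_to_ref + err_to_alt
    return ref, alt


def simulate_wga_readcounts(
    truth_genotypes: pd.DataFrame,
    wga_profile: WgaProfile,
    het_snp_positions: pd.DataFrame | None = None,
    seed=0,
) -> pd.DataFrame:
    """Simulate per-cell allele depths under a WGA chemistry profile.

    Two usage modes:

    * ``het_snp_positions`` given: simulate germline het-SNP read counts
      (every cell truly heterozygous at every listed position); the truth
      genotype matrix only supplies the cell names.  Returns a long table
      (cell, chrom, pos, ref_depth, alt_depth).
    * ``het_snp_positions`` omitted: simulate read counts at the somatic
      sites of the truth genotype matrix (het where mutated, hom-ref
      otherwise).  Returns a long table (cell, site, ref_depth, alt_depth).
    """
    rng = as_rng(seed)
    if truth_genotypes.shape[0] == 0:
        raise ValueError("empty genotype matrix")
    cells = list(truth_genotypes.index)
    if het_snp_positions is not None:
        if het_snp_positions.duplicated(["chrom", "pos"]).any():
            raise ValueError("het SNP positions must be unique per chromosome")
        n_sites = len(het_snp_positions)
        geno = np.ones((len(cells), n_sites), dtype=np.int8)
        ref, alt = _simulate_depth_arrays(geno, wga_profile, rng)
        out = pd.DataFrame({
            "cell": np.repeat(cells, n_sites),
            "chrom": np.tile(het_snp_positions["chrom"].to_numpy(), len(cells)),
            "pos": np.tile(het_snp_positions["pos"].to_numpy(), len(cells)),
            "ref_depth": ref.ravel(),
            "alt_depth": alt.ravel(),
        })
        return out
    geno = truth_genotypes.to_numpy(dtype=np.int8)
    ref, alt = _simulate_depth_arrays(geno, wga_profile, rng)
    sites = list(truth_genotypes.columns)
    return pd.DataFrame({
        "cell": np.repeat(cells, len(sites)),
        "site": np.tile(sites, len(cells)),
        "ref_depth": ref.ravel(),
        "alt_depth": alt.ravel(),
    })


def inject_cnv(readcounts: pd.DataFrame, truth: CloneTruth, event: CnvEvent,
               seed=0, amp_error_rate: float = 1e-3) -> pd.DataFrame:
    """Apply a hemizygous deletion to a het-SNP allele-depth table.

    In carrier cells (cells of ``event.clone``), the lost haplotype's allele
    depth inside the half-open interval is replaced by amplification-error
    background only.  The lost allele at each SNP follows a per-site phase
    drawn once, so all carriers lose the same allele at the same site.
    Non-carrier cells are untouched.  If the interval covers no het site a
    warning is raised and the input is returned unchanged.
    """
    rng = as_rng(seed)
    out = readcounts.copy()
    in_region = ((out["chrom"] == event.chrom)
                 & (out["pos"] >= event.start) & (out["pos"] < event.end))
    sites = np.sort(out.loc[in_region, "pos"].unique())
    if len(sites) == 0:
        warnings.warn("CNV interval overlaps no het site; no-op", stacklevel=2)
        return out
    carriers = {c for c, k in truth.clone_of_cell.items() if k == event.clone}
    # phase: which observed allele sits on the lost haplotype, per site
    lost_is_alt = pd.Series(rng.random(len(sites)) < 0.5, index=sites)
    mask = in_region & out["cell"].isin(carriers)
    idx = out.index[mask]
    la = lost_is_alt.loc[out.loc[idx, "pos"]].to_numpy()
    total = (out.loc[idx, "ref_depth"] + out.loc[idx, "alt_depth"]).to_numpy()
    background = rng.binomial(total, amp_error_rate)
    kept_ref = out.loc[idx, "ref_depth"].to_numpy().copy()
    kept_alt = out.loc[idx, "alt_depth"].to_numpy().copy()
    # deleted haplotype keeps only error reads; surviving one takes the depth
    new_alt = np.where(la, background, kept_alt + kept_ref - background)
    new_ref = total - new_alt
    out.loc[idx, "ref_depth"] = new_ref
    out.loc[idx, "alt_depth"] = new_alt
    truth.cnv_events.append(event)
    return out


@dataclass
class UmiFamily:
    """Reads sharing one unique molecular identifier at one site."""

    umi: str
    site: int
    reads: list
    true_allele: str = ""

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class UmiFamilySet:
    families: list
    ref_seq: str
    variant_pos: int
    ref_base: str
    alt_base: str

    def __iter__(self):
        return iter(self.families)

    def __len__(self):
        return len(self.families)


def default_family_size_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    """Truncated (>=1) negative binomial family sizes, mean ~5."""
    s = rng.negative_binomial(2, 0.3, size=size)
    return np.maximum(s, 1)


def simulate_umi_families(
    true_vafs: Sequence[float] | float,
    n_molecules: int,
    reads_per_family_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    per_read_error: float = 0.01,
    seed=0,
    read_length: int = 12,
) -> list:
    """Simulate UMI read families at one or more variant sites.

    Each original molecule is assigned the alternate allele with probability
    equal to the site VAF; every read of the family copies the molecule with
    independent per-base errors (uniform over the three other bases).

    Returns a list of :class:`UmiFamilySet`, one per VAF supplied.
    """
    rng = as_rng(seed)
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if per_read_error < 0:
        raise ValueError("per_read_error must be non-negative")
    vafs = np.atleast_1d(np.asarray(true_vafs, dtype=float))
    if np.any((vafs < 0) | (vafs > 1)):
        raise ValueError("VAFs must lie in [0,1]")
    if reads_per_family_dist is None:
        reads_per_family_dist = default_family_size_dist
    bases = np.array(list("ACGT"))
    out = []
    vpos = read_length // 2
    for si, vaf in enumerate(vafs):
        ref_idx = rng.integers(0, 4, size=read_length)
        ref_seq = "".join(bases[ref_idx])
        ref_base = ref_seq[vpos]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        is_alt = rng.random(n_molecules) < vaf
        sizes = np.asarray(reads_per_family_dist(rng, n_molecules), dtype=int)
        # one row per read: copy the molecule template, then flip error
        # positions to one of the three other bases (vectorized)
        templates = np.tile(ref_idx, (n_molecules, 1))
        templates[is_alt, vpos] = int(np.where(bases == alt_base)[0][0])
        reads_idx = np.repeat(templates, sizes, axis=0)
        if per_read_error > 0:
            err = rng.random(reads_idx.shape) < per_read_error
            shift = rng.integers(1, 4, size=reads_idx.shape)
            reads_idx = np.where(err, (reads_idx + shift) % 4, reads_idx)
        read_strs = ["".join(row) for row in bases[reads_idx]]
        fams = []
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for mi in range(n_molecules):
            fams.append(UmiFamily(
                umi=f"umi{si}_{mi}", site=si,
                reads=read_strs[offsets[mi]:offsets[mi + 1]],
                true_allele=alt_base if is_alt[mi] else ref_base))
        out.append(UmiFamilySet(families=fams, ref_seq=ref_seq,
                                variant_pos=vpos, ref_base=ref_base,
                                alt_base=alt_base))
    return out


def simulate_phenotypes(cell_tree: dendropy.Tree, n_markers: int,
                        bm_rate: float, noise_sd: float, seed=0,
                        root_value: float = 0.0) -> pd.DataFrame:
    """Brownian-motion trait evolution along a tree plus i.i.d. tip noise.

    With ``noise_sd = 0`` the trait covariance between two tips equals
    ``bm_rate`` times their shared root-to-MRCA path length.
    """
    rng = as_rng(seed)
    if bm_rate < 0 or noise_sd < 0:
        raise ValueError("bm_rate and noise_sd must be non-negative")
    for e in cell_tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("tree has negative branch lengths")
    tips, values = [], []
    node_val = {}
    for _ in range(n_markers):
        col = {}
        for nd in cell_tree.preorder_node_iter():
            if nd.parent_node is None:
                col[id(nd)] = root_value
            else:
                bl = nd.edge.length or 0.0
                col[id(nd)] = col[id(nd.parent_node)] + rng.normal(0.0, np.sqrt(bm_rate * bl))
        node_val[_] = col
    for leaf in cell_tree.leaf_node_iter():
        tips.append(leaf.taxon.label)
        values.append([node_val[m][id(leaf)] for m in range(n_markers)])
    X = np.asarray(values) + rng.normal(0.0, noise_sd, size=(len(tips), n_markers))
    return pd.DataFrame(X, index=tips,
                        columns=[f"marker{m}" for m in range(n_markers)])


def genotype_calls_from_depths(readcounts: pd.DataFrame, min_alt: int = 2,
                               min_depth: int = 5,
                               site_col: str = "site") -> pd.DataFrame:
    """Ternary calls (1 alt-carrying, 0 ref, NaN missing) from a depth table."""
    total = readcounts["ref_depth"] + readcounts["alt_depth"]
    call = np.where(total < min_depth, np.nan,
                    (readcounts["alt_depth"] >= min_alt).astype(float))
    tmp = readcounts[["cell", site_col]].copy()
    tmp["call"] = call
    return tmp.pivot(index="cell", columns=site_col, values="call")
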