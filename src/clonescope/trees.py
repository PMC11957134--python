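"""Cell phylogenies from somatic genotype matrices, and tree-based inference.

Covers reconstruction (neighbor-joining on mutation-sharing distances with
pairwise deletion of missing genotypes; exhaustive maximum parsimony for
small cell counts), site-resampling bootstrap supports, topology
diagnostics (node distances, Robinson-Foulds), tumor-monophyly testing,
Poisson-branch Bayesian time calibration, a generalized-skyline effective
population size estimator, Blomberg's-K phenotype heritability, and a
phylogeny-based shared/private mutation filter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare
from scipy import stats

from .simulate import as_rng

__all__ = [
    "OUTGROUP",
    "build_tree",
    "mutation_distance_matrix",
    "bootstrap_support",
    "tree_splits",
    "rf_distance",
    "node_distance_matrix",
    "test_monophyly",
    "MonophylyResult",
    "correlate_branch_time",
    "time_calibrate",
    "TimeTree",
    "skyline_ne",
    "blomberg_k",
    "phylogeny_filter",
]

OUTGROUP = "OUTGROUP_REF"


# ---------------------------------------------------------------------------
# distances and reconstruction

def mutation_distance_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise mutation-sharing distance between cells.

    For cells i, j over sites where both are genotyped (pairwise
    deletion): d = (# mutations private to i + private to j) scaled by the
    inverse co-covered fraction, so distances stay on the expected
    mutation-count scale under random missingness.
    """
    X = genotypes.to_numpy(dtype=float)
    cells = list(genotypes.index)
    n = len(cells)
    obs = ~np.isnan(X)
    Xz = np.nan_to_num(X, nan=0.0)
    D = np.zeros((n, n))
    n_sites = X.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = both.sum()
            if m == 0:
                raise ValueError(f"cells {cells[i]}, {cells[j]} share no genotyped site")
            diff = np.sum(np.abs(Xz[i, both] - Xz[j, both]))
            D[i, j] = D[j, i] = diff * (n_sites / m)
    return pd.DataFrame(D, index=cells, columns=cells)


def _nj_from_distances(D: pd.DataFrame) -> dendropy.Tree:
    # scikit-bio's NJ is fully array-based, hence deterministic under ties
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(D.to_numpy(dtype=float), ids=list(D.index))
    newick = str(nj(dm))
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _add_outgroup(genotypes: pd.DataFrame) -> pd.DataFrame:
    og = pd.DataFrame(np.zeros((1, genotypes.shape[1])),
                      index=[OUTGROUP], columns=genotypes.columns)
    return pd.concat([genotypes, og])


def build_tree(genotypes: pd.DataFrame, method: str = "nj",
               outgroup: str | None = None, keep_outgroup: bool = False) -> dendropy.Tree:
    """Reconstruct a rooted cell tree from a cells x variants matrix.

    Entries are 1 (mutation present), 0 (absent) or NaN (missing,
    uninformative).  Default method is neighbor-joining on the pairwise
    mutation-sharing distance, rooted on ``outgroup`` (a normal cell) or,
    when none is named, on an all-reference pseudo-cell that is pruned
    again after rooting.  ``method='parsimony'`` runs an exhaustive
    Fitch-parsimony search (<= 8 cells).  Branch lengths are on the
    expected-mutation-count scale (parsimony: unit lengths).
    """
    if genotypes.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    added_og = False
    if outgroup is None:
        genotypes = _add_outgroup(genotypes)
        outgroup = OUTGROUP
        added_og = True
    if method == "nj":
        D = mutation_distance_matrix(genotypes)
        ingroup = [c for c in D.index if c != outgroup]
        if np.allclose(D.loc[ingroup, ingroup].to_numpy(), 0.0):
            warnings.warn("all cells identical; star tree returned", stacklevel=2)
        tree = _nj_from_distances(D)
        for e in tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                e.length = 0.0
    elif method == "parsimony":
        tree = _exhaustive_parsimony(genotypes)
    else:
        raise ValueError(f"unknown method {method!r}")

    og = tree.find_node_with_taxon_label(outgroup)
    tree.to_outgroup_position(og, update_bipartitions=False)
    if added_og and not keep_outgroup:
        tree.prune_taxa_with_labels([outgroup])
    tree.is_rooted = True
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def _fitch_length(topology_children: dict, root, tip_states: dict) -> int:
    """Fitch small-parsimony count for one binary character."""
    changes = 0

    def post(node):
        nonlocal changes
        if node in tip_states:
            return tip_states[node]
        sets = [post(c) for c in topology_children[node]]
        inter = frozenset.intersection(*sets)
        if inter:
            return inter
        changes += len(sets) - 1 if len(sets) > 2 else 1
        return frozenset.union(*sets)

    post(root)
    return changes


def _exhaustive_parsimony(genotypes: pd.DataFrame) -> dendropy.Tree:
    cells = list(genotypes.index)
    if len(cells) > 8:
        raise ValueError("exhaustive parsimony limited to 8 cells")
    X = genotypes.to_numpy(dtype=float)

    # enumerate unrooted topologies by stepwise addition, as nested tuples
    def topologies(taxa):
        if len(taxa) <= 3:
            yield tuple(taxa)
            return
        *rest, last = taxa
        for base in topologies(rest):
            for t in _insertions(base, last):
                yield t

    def _insertions(tree, leaf):
        # tree is a tuple (multifurcating root of 3 for unrooted)
        for i, sub in enumerate(tree):
            for new_sub in _insert_into(sub, leaf):
                yield tree[:i] + (new_sub,) + tree[i + 1:]

    def _insert_into(sub, leaf):
        yield (sub, leaf)
        if isinstance(sub, tuple):
            for i, child in enumerate(sub):
                for new_child in _insert_into(child, leaf):
                    yield sub[:i] + (new_child,) + sub[i + 1:]

    def score(topo):
        children: dict = {}
        tips = {}
        counter = itertools.count()

        def build(sub):
            if not isinstance(sub, tuple):
                tips[sub] = None
                return sub
            node = f"__n{next(counter)}"
            children[node] = [build(c) for c in sub]
            return node

        root = build(topo)
        total = 0
        for j in range(X.shape[1]):
            ts = {}
            for c in cells:
                v = X[cells.index(c), j]
                ts[c] = frozenset({0, 1}) if np.isnan(v) else frozenset({int(v)})
            total += _fitch_length(children, root, ts)
        return total

    best, best_score = None, None
    for topo in topologies(cells):
        s = score(topo)
        if best_score is None or s < best_score:
            best, best_score = topo, s

    def to_newick(sub):
        if not isinstance(sub, tuple):
            return f"{sub}:1.0"
        return "(" + ",".join(to_newick(c) for c in sub) + "):1.0"

    nwk = "(" + ",".join(to_newick(c) for c in best) + ");"
    return dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# supports and topology diagnostics

def tree_splits(tree: dendropy.Tree, nontrivial_only: bool = True) -> set:
    """Rooted clades of a tree as frozensets of tip labels."""
    all_tips = {l.taxon.label for l in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_internal_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        if nontrivial_only and (len(tips) < 2 or tips == all_tips):
            continue
        out.add(tips)
    return out


def bootstrap_support(genotypes: pd.DataFrame, n_reps: int = 100,
                      method: str = "nj", outgroup: str | None = None,
                      seed=0) -> tuple[dendropy.Tree, dict]:
    """Site-resampling bootstrap supports for the point-estimate tree.

    Variant columns are resampled with replacement ``n_reps`` times; the
    support of each clade of the point tree is the percentage of replicate
    trees containing it.  Supports are attached to internal nodes as
    ``node.support`` and returned as a dict clade -> percent.
    """
    if genotypes.shape[1] < 10:
        raise ValueError("need >= 10 variant sites for a meaningful bootstrap")
    rng = as_rng(seed)
    point = build_tree(genotypes, method=method, outgroup=outgroup)
    target = tree_splits(point)
    counts = {s: 0 for s in target}
    for _ in range(n_reps):
        cols = rng.choice(genotypes.shape[1], size=genotypes.shape[1], replace=True)
        rep = genotypes.iloc[:, cols]
        rep.columns = [f"s{i}" for i in range(rep.shape[1])]
        rep_tree = build_tree(rep, method=method, outgroup=outgroup)
        rep_splits = tree_splits(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    all_tips = {l.taxon.label for l in point.leaf_node_iter()}
    for node in point.preorder_internal_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        if tips in support:
            node.support = support[tips]
            node.label = f"{support[tips]:.0f}"
    return point, support


def rf_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) distance."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=tree1.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=tree2.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    for t in (t1, t2):
        t.is_rooted = False
        t.update_bipartitions(suppress_unifurcations=True)
    return int(treecompare.symmetric_difference(t1, t2))


def node_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise topological (edge-count) distances between tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(pdm.path_edge_count(taxa[i], taxa[j]))
            D[i, j] = D[j, i] = d
    labels = [t.label for t in taxa]
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass
class MonophylyResult:
    monophyletic: bool
    clade_tips: frozenset
    support: float | None = None
    trivial: bool = False


def test_monophyly(tree: dendropy.Tree, malignant_labels,
                   supports: dict | None = None) -> MonophylyResult:
    """Is the smallest clade containing all malignant tips malignant-only?

    ``malignant_labels`` maps tip label -> bool.  With a single label
    class the verdict is trivially monophyletic (flagged).  ``supports``
    (clade -> percent, from :func:`bootstrap_support`) attaches the
    support of the minimal clade.
    """
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in malignant_labels]
    if missing:
        raise ValueError(f"unlabeled tips: {missing[:3]}...")
    malignant = [t for t in tips if malignant_labels[t]]
    others = [t for t in tips if not malignant_labels[t]]
    if not malignant or not others:
        return MonophylyResult(True, frozenset(malignant or others), trivial=True)
    tree.is_rooted = True  # MRCA is only meaningful on a rooted tree
    mrca = tree.mrca(taxon_labels=malignant)
    clade = frozenset(l.taxon.label for l in mrca.leaf_iter())
    verdict = clade == frozenset(malignant)
    sup = supports.get(clade) if supports else getattr(mrca, "support", None)
    return MonophylyResult(verdict, clade, sup)


def root_to_tip_lengths(tree: dendropy.Tree) -> pd.Series:
    vals = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        vals[leaf.taxon.label] = d
    return pd.Series(vals)


def correlate_branch_time(tree: dendropy.Tree, culture_times,
                          n_perm: int = 10000, seed=0) -> dict:
    """Spearman correlation of root-to-tip path length vs culture days.

    Returns rho, the analytic p, and a permutation p-value; flags
    underpowered inputs (< 3 tips) and constant times (undefined).
    """
    lens = root_to_tip_lengths(tree)
    times = pd.Series(dict(culture_times)) if not isinstance(culture_times, pd.Series) \
        else culture_times
    missing = [t for t in lens.index if t not in times.index]
    if missing:
        raise ValueError(f"culture times missing for {missing[:3]}")
    times = times.loc[lens.index]
    if times.nunique() == 1:
        warnings.warn("constant culture times; correlation undefined", stacklevel=2)
        return {"rho": float("nan"), "p": float("nan"), "p_perm": float("nan"),
                "flag": "constant_times"}
    rho, p = stats.spearmanr(lens.to_numpy(), times.to_numpy())
    rng = as_rng(seed)
    t = times.to_numpy()
    hits = 0
    for _ in range(n_perm):
        r, _p = stats.spearmanr(lens.to_numpy(), rng.permutation(t))
        if abs(r) >= abs(rho):
            hits += 1
    out = {"rho": float(rho), "p": float(p),
           "p_perm": (hits + 1) / (n_perm + 1), "flag": ""}
    if len(lens) < 3:
        out["flag"] = "underpowered"
    return out


# ---------------------------------------------------------------------------
# time calibration

@dataclass
class TimeTree:
    """Posterior time-calibrated tree.

    tree : dendropy.Tree with edge lengths = posterior mean durations (years)
    rate_samples : posterior draws of the mutation rate (mutations/year)
    node_age_samples : DataFrame (samples x nodes) of time-from-root ages
    """

    tree: dendropy.Tree
    rate_samples: np.ndarray
    node_age_samples: pd.DataFrame
    anchors: dict = field(default_factory=dict)

    def node_age_summary(self, ci: float = 0.90) -> pd.DataFrame:
        lo = (1 - ci) / 2
        q = self.node_age_samples.quantile([lo, 0.5, 1 - lo]).T
        q.columns = ["lower", "median", "upper"]
        q["mean"] = self.node_age_samples.mean()
        return q


def _node_key(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def time_calibrate(tree: dendropy.Tree,
                   rate_prior: tuple[float, float] | None = (0.01, 0.01),
                   anchors: dict | None = None, fixed_rate: float | None = None,
                   n_samples: int = 1000, burn_in: int = 200,
                   n_anchor_sweeps: int = 10, seed=0) -> TimeTree:
    """Bayesian Poisson-branch time calibration by Gibbs sampling.

    Branch mutation counts m are modeled m ~ Poisson(lambda * t) with a
    Gamma(shape, rate) prior on the mutation rate lambda (mutations/year)
    and flat priors on branch durations t, giving conjugate conditionals
    lambda | t ~ Gamma(a0 + sum m, b0 + sum t) and t | lambda ~
    Gamma(m + 1, lambda).

    ``anchors`` maps tip label -> known root-to-tip age in years (or a
    (lo, hi) tuple for a uniform age prior); after each duration draw the
    branches on anchored tips' paths are rescaled (``n_anchor_sweeps``
    cycles) so every anchored path sum hits its (drawn) anchor age, which
    makes node ages identifiable.  Without anchors an informative rate
    prior (or ``fixed_rate``) is required; the default rate prior is
    weakly informative and does not identify the time scale on its own.
    """
    rng = as_rng(seed)
    anchors = dict(anchors or {})
    if not anchors and fixed_rate is None and rate_prior is None:
        raise ValueError("non-identifiable: provide anchors or an informative rate prior")

    # collect edges (skip rootmost edge without length)
    edges = []
    for e in tree.preorder_edge_iter():
        if e.length is None:
            continue
        edges.append(e)
    m = np.array([max(0, int(round(e.length))) for e in edges], dtype=float)
    keys = [_node_key(e.head_node) or f"edge{i}" for i, e in enumerate(edges)]
    eidx = {id(e): i for i, e in enumerate(edges)}

    # root-to-tip edge paths for anchored tips
    anchor_paths = {}
    for tip_label, age in anchors.items():
        leaf = tree.find_node_with_taxon_label(tip_label)
        if leaf is None:
            raise ValueError(f"anchor tip {tip_label!r} not in tree")
        path = []
        node = leaf
        while node.parent_node is not None:
            if id(node.edge) in eidx:
                path.append(eidx[id(node.edge)])
            node = node.parent_node
        anchor_paths[tip_label] = (path, age)

    lam = fixed_rate if fixed_rate is not None else max(m.sum(), 1.0) / max(len(m), 1)
    t = (m + 1.0) / lam
    a0, b0 = rate_prior if rate_prior is not None else (0.0, 0.0)

    rate_draws = []
    age_draws = []
    node_keys_all = []
    for nd in tree.preorder_node_iter():
        node_keys_all.append(_node_key(nd) or "root")

    total = burn_in + n_samples
    for it in range(total):
        t = rng.gamma(m + 1.0, 1.0 / lam)
        targets = {tip: (age if np.isscalar(age) else float(rng.uniform(*age)))
                   for tip, (path, age) in anchor_paths.items()}
        # cycle until all anchored path-sum constraints hold jointly
        for _ in range(n_anchor_sweeps if anchor_paths else 0):
            for tip_label, (path, _age) in anchor_paths.items():
                cur = t[path].sum()
                if cur > 0:
                    t[path] *= targets[tip_label] / cur
        if fixed_rate is None:
            lam = rng.gamma(a0 + m.sum(), 1.0 / (b0 + t.sum()))
        if it >= burn_in:
            rate_draws.append(lam)
            ages = {}
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    ages[_node_key(nd) or "root"] = 0.0
                else:
                    parent_age = ages[_node_key(nd.parent_node) or "root"]
                    dur = t[eidx[id(nd.edge)]] if id(nd.edge) in eidx else 0.0
                    ages[_node_key(nd) or "root"] = parent_age + dur
            age_draws.append(ages)

    node_age_samples = pd.DataFrame(age_draws)
    out_tree = tree.clone(depth=1)
    mean_ages = node_age_samples.mean()
    for nd in out_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        k_child = _node_key(nd) or "root"
        k_par = _node_key(nd.parent_node) or "root"
        nd.edge.length = float(mean_ages[k_child] - mean_ages[k_par])
    return TimeTree(tree=out_tree, rate_samples=np.asarray(rate_draws),
                    node_age_samples=node_age_samples, anchors=anchors)


# ---------------------------------------------------------------------------
# skyline

def _coalescent_intervals(tree: dendropy.Tree) -> pd.DataFrame:
    """Interval table (k lineages, width) from an ultrametric-in-time tree."""
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(update_bipartitions=False)
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    tip_depth = np.mean([depths[l] for l in tree.leaf_node_iter()])
    # time before sampling
    coal_times = sorted(tip_depth - depths[nd]
                        for nd in tree.preorder_internal_node_iter())
    n = len(list(tree.leaf_node_iter()))
    rows = []
    prev = 0.0
    k = n
    for ct in coal_times:
        rows.append({"k": k, "width": max(ct - prev, 0.0), "t_start": prev,
                     "t_end": ct})
        prev = ct
        k -= 1
    return pd.DataFrame(rows)


def _skyline_loglik(groups: list, intervals: pd.DataFrame) -> tuple[float, list]:
    ll = 0.0
    nes = []
    for g in groups:
        sub = intervals.iloc[g]
        k = sub["k"].to_numpy()
        w = sub["width"].to_numpy()
        ne = float(np.sum(k * (k - 1) * w / 2.0) / len(sub))
        ne = max(ne, 1e-12)
        rate = k * (k - 1) / (2.0 * ne)
        ll += float(np.sum(np.log(np.maximum(rate, 1e-300)) - rate * w))
        nes.append(ne)
    return ll, nes


def skyline_ne(time_tree, epsilon: float | None = None,
               tree_samples: list | None = None, n_grid: int = 50) -> pd.DataFrame:
    """Generalized-skyline effective population size through time.

    Classic skyline: with k extant lineages over a coalescent interval of
    width w, N-hat = k(k-1)w/2 for that event.  Adjacent intervals are
    pooled until each group spans at least ``epsilon`` time units; when
    ``epsilon`` is None it is chosen by AICc over a grid (Strimmer-Pybus
    style model selection).  Returns one row per epoch with t_start/t_end
    (time before sampling) and ne; when ``tree_samples`` (posterior time
    trees) are given, 2.5/97.5% quantile columns are added from their
    per-epoch trajectories evaluated on the point tree's epochs.
    """
    tree = time_tree.tree if isinstance(time_tree, TimeTree) else time_tree
    n_tips = len(list(tree.leaf_node_iter()))
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    if n_tips < 5:
        warnings.warn("fewer than 5 tips; skyline underpowered", stacklevel=2)
    intervals = _coalescent_intervals(tree)

    def group_by_eps(eps: float) -> list:
        groups, cur, span = [], [], 0.0
        for i, wd in enumerate(intervals["width"]):
            cur.append(i)
            span += wd
            if span >= eps:
                groups.append(cur)
                cur, span = [], 0.0
        if cur:
            if groups:
                groups[-1].extend(cur)
            else:
                groups.append(cur)
        return groups

    if epsilon is None:
        total_span = intervals["width"].sum()
        best = (None, -np.inf, None)
        for eps in np.linspace(0.0, total_span / 2.0, n_grid):
            groups = group_by_eps(eps)
            ll, nes = _skyline_loglik(groups, intervals)
            p = len(groups)
            nobs = len(intervals)
            if nobs - p - 1 <= 0:
                continue
            aicc = -2 * ll + 2 * p + 2 * p * (p + 1) / (nobs - p - 1)
            if -aicc > best[1]:
                best = (groups, -aicc, eps)
        groups, _, epsilon = best
        if groups is None:
            groups = [[i] for i in range(len(intervals))]
    else:
        groups = group_by_eps(epsilon)

    _, nes = _skyline_loglik(groups, intervals)
    rows = []
    for g, ne in zip(groups, nes):
        sub = intervals.iloc[g]
        rows.append({"t_start": float(sub["t_start"].iloc[0]),
                     "t_end": float(sub["t_end"].iloc[-1]),
                     "n_events": len(g), "ne": ne})
    out = pd.DataFrame(rows)
    if tree_samples:
        mids = (out["t_start"] + out["t_end"]) / 2.0
        trajs = []
        for ts in tree_samples:
            rep = skyline_ne(ts, epsilon=epsilon)
            vals = []
            for tmid in mids:
                hit = rep[(rep["t_start"] <= tmid) & (rep["t_end"] >= tmid)]
                vals.append(hit["ne"].iloc[0] if len(hit) else np.nan)
            trajs.append(vals)
        T = np.asarray(trajs, dtype=float)
        out["ne_lo"] = np.nanpercentile(T, 2.5, axis=0)
        out["ne_hi"] = np.nanpercentile(T, 97.5, axis=0)
    return out


# ---------------------------------------------------------------------------
# phylogenetic signal

def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic variance-covariance: shared root-to-MRCA path lengths."""
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    V = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i in range(n):
        V[i, i] = depths[leaves[i]]
        for j in range(i + 1, n):
            mrca = pdm.mrca(leaves[i].taxon, leaves[j].taxon)
            V[i, j] = V[j, i] = depths[mrca]
    return pd.DataFrame(V, index=labels, columns=labels)


def _k_statistic(x: np.ndarray, Vinv: np.ndarray, trV: float,
                 sum_vinv: float, expected_ratio: float) -> float:
    n = len(x)
    ones = np.ones(n)
    ahat = float(ones @ Vinv @ x / (ones @ Vinv @ ones))
    dev = x - ahat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Vinv @ dev) / (n - 1)
    return (mse0 / mse) / expected_ratio


def blomberg_k(tree: dendropy.Tree, trait, n_perm: int = 999, seed=0) -> dict:
    """Blomberg's K phylogenetic signal with a tip-permutation test.

    K compares the observed ratio of phylogenetically uncorrected to
    GLS-corrected trait variance with its Brownian-motion expectation on
    the same tree; K ~ 1 under BM, < 1 for weak signal.  The p-value is
    the one-sided fraction of trait permutations across tips reaching an
    equal or larger K.
    """
    trait = pd.Series(dict(trait)) if not isinstance(trait, pd.Series) else trait
    V = phylo_vcv(tree)
    x = trait.loc[V.index].to_numpy(dtype=float)
    if np.allclose(x.var(), 0.0):
        warnings.warn("constant trait; K undefined", stacklevel=2)
        return {"K": float("nan"), "p": float("nan")}
    Vm = V.to_numpy()
    Vinv = np.linalg.inv(Vm)
    n = len(x)
    trV = float(np.trace(Vm))
    sum_vinv = float(Vinv.sum())
    expected_ratio = (trV - n / sum_vinv) / (n - 1)
    k_obs = _k_statistic(x, Vinv, trV, sum_vinv, expected_ratio)
    rng = as_rng(seed)
    hits = 0
    for _ in range(n_perm):
        k_p = _k_statistic(rng.permutation(x), Vinv, trV, sum_vinv, expected_ratio)
        if k_p >= k_obs:
            hits += 1
    return {"K": float(k_obs), "p": (hits + 1) / (n_perm + 1)}


# ---------------------------------------------------------------------------
# phylogeny-based variant filter

def phylogeny_filter(genotypes: pd.DataFrame, tree: dendropy.Tree) -> pd.DataFrame:
    """Classify variants as shared/private and flag homoplasy.

    A variant is ``private`` when carried by a single cell and ``shared``
    otherwise.  A shared variant is mapped to the branch subtending the
    smallest clade whose genotyped tips match the carriers; if no such
    clade exists (the carriers straddle the tree), the variant is flagged
    homoplasic -- the signature of independent WGA errors rather than a
    heritable mutation.
    """
    clades = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        label = _node_key(node) or "?"
        clades.append((tips, label))
    clades.sort(key=lambda c: len(c[0]))

    rows = []
    for var in genotypes.columns:
        col = genotypes[var]
        carriers = frozenset(col.index[col == 1])
        missing = frozenset(col.index[col.isna()])
        if len(carriers) <= 1:
            rows.append({"variant": var, "klass": "private",
                         "branch": next(iter(carriers), None), "homoplasic": False})
            continue
        branch, homoplasic = None, True
        for tips, label in clades:
            if carriers <= tips and (tips - carriers) <= missing:
                branch, homoplasic = label, False
                break
        rows.append({"variant": var, "klass": "shared", "branch": branch,
                     "homoplasic": homoplasic})
    return pd.DataFrame(rows).set_index("variant")
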