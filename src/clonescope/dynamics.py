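"""Wright-Fisher clone dynamics and ABC inference of onset time and selection.

A mutant clone seeded as a single cell at generation ``t0`` evolves by
binomial resampling with selection-weighted expectation
p' = p(1+s) / (1 + p s); rejection ABC matches coalescent-informed tree
summaries (sampled clone fraction, clone MRCA age, mean within-clone
pairwise coalescent time) between observed and simulated data to recover
(t0, s) posteriors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import as_rng

__all__ = [
    "WfParams",
    "wf_simulate",
    "sample_clone_coalescent",
    "tree_summaries",
    "CloneTrajectoryPosterior",
    "abc_infer",
]


@dataclass(frozen=True)
class WfParams:
    """Wright-Fisher forward-simulation parameters.

    population_size_trajectory
        Total population size N(t) per generation (length = total
        generations); a scalar is broadcast.
    selection_coefficient
        s >= -1; relative fitness of the clone is (1+s).
    onset_generation
        Generation at which the clone is seeded at frequency 1/N(t0).
    generations_total
        Number of generations simulated (sampling happens at the end).
    """

    population_size_trajectory: Sequence[int] | int
    selection_coefficient: float = 0.0
    onset_generation: int = 0
    generations_total: int = 100
    seed: int | None = None
    #: override of the onset frequency (default: a single cell, 1/N(t0))
    initial_frequency: float | None = None

    def n_at(self) -> np.ndarray:
        N = np.asarray(self.population_size_trajectory)
        if N.ndim == 0:
            N = np.full(self.generations_total, int(N))
        if len(N) < self.generations_total:
            raise ValueError("population size trajectory shorter than generations_total")
        if (N < 1).any():
            raise ValueError("population sizes must be >= 1")
        return N.astype(np.int64)

    def __post_init__(self):
        if self.selection_coefficient < -1:
            raise ValueError("selection coefficient must be >= -1")
        if self.onset_generation < 0:
            raise ValueError("onset generation must be >= 0")


def wf_simulate(params: WfParams, seed=None) -> np.ndarray:
    """Forward-simulate the clone frequency trajectory.

    Returns an array of length ``generations_total + 1`` with the clone
    frequency after each generation (index 0 = before onset, always 0
    unless onset is at 0).  Extinction simply leaves the trajectory at 0.
    """
    rng = as_rng(seed if seed is not None else params.seed)
    N = params.n_at()
    T = params.generations_total
    s = params.selection_coefficient
    freq = np.zeros(T + 1)
    if params.onset_generation >= T:
        return freq
    p = (params.initial_frequency if params.initial_frequency is not None
         else 1.0 / N[params.onset_generation])
    if not (0.0 <= p <= 1.0):
        raise ValueError("initial frequency must lie in [0,1]")
    freq[params.onset_generation] = p
    for g in range(params.onset_generation, T):
        if p in (0.0, 1.0):
            freq[g + 1] = p
            continue
        expected = p * (1 + s) / (1 + p * s)
        k = rng.binomial(N[g], min(max(expected, 0.0), 1.0))
        p = k / N[g]
        freq[g + 1] = p
    return freq


def sample_clone_coalescent(clone_sizes: np.ndarray, n_tips: int, seed=None,
                            generation_time_days: float = 1.0) -> dict:
    """Coalesce sampled clone lineages backward through a size trajectory.

    ``clone_sizes`` is the clone's absolute size per generation (forward
    time); lineages coalesce per generation with probability
    k(k-1)/(2 * size).  Returns the clone MRCA age and the mean pairwise
    coalescent time of the sample, in days before sampling.
    """
    rng = as_rng(seed)
    sizes = np.asarray(clone_sizes, dtype=float)
    T = len(sizes)
    k = int(n_tips)
    if k < 2:
        return {"mrca_age": np.nan, "mean_pairwise_coal": np.nan}
    pair_times = []
    mrca_age = None
    active = k
    for back in range(1, T + 1):
        size = max(sizes[T - back], 1.0)
        rate = active * (active - 1) / (2.0 * size)
        n_coal = min(active - 1, rng.poisson(min(rate, active)))
        for _ in range(int(n_coal)):
            # merging two random lineages: record (active choose 2) pair ages
            pair_times.extend([back] * (active - 1))
            active -= 1
        if active == 1:
            mrca_age = back
            break
    if mrca_age is None:
        mrca_age = T  # clone founder bounds all coalescences
        while active > 1:
            pair_times.extend([T] * (active - 1))
            active -= 1
    mean_pair = float(np.mean(pair_times)) if pair_times else float(mrca_age)
    g = generation_time_days
    return {"mrca_age": mrca_age * g, "mean_pairwise_coal": mean_pair * g}


def tree_summaries(time_tree, clone_tips: Sequence[str],
                   tip_sets_by_timepoint: dict | None = None) -> dict:
    """Summary statistics of one clone on a time-calibrated tree.

    Returns the clone tip fraction (overall and per timepoint when
    ``tip_sets_by_timepoint`` maps timepoint -> tip labels), the clone
    MRCA age, and the mean within-clone pairwise coalescent time, all in
    the tree's time units before sampling.
    """
    tree = getattr(time_tree, "tree", time_tree)
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    clone_tips = [t for t in clone_tips]
    if not set(clone_tips) <= set(tips):
        raise ValueError("clone tips absent from tree")
    if len(clone_tips) == 0:
        raise ValueError("empty clone")
    depths = {}
    for nd in tree.preorder_node_iter():
        depths[nd] = (0.0 if nd.parent_node is None
                      else depths[nd.parent_node] + (nd.edge.length or 0.0))
    leaf_by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
    tip_depth = float(np.mean([depths[l] for l in tree.leaf_node_iter()]))
    out = {"tip_fraction": len(clone_tips) / len(tips)}
    if tip_sets_by_timepoint:
        for tp, tset in tip_sets_by_timepoint.items():
            tset = set(tset)
            out[f"tip_fraction_{tp}"] = (len(tset & set(clone_tips)) / len(tset)
                                         if tset else np.nan)
    if len(clone_tips) == 1:
        warnings.warn("singleton clone: coalescent summaries undefined", stacklevel=2)
        out["mrca_age"] = 0.0
        out["mean_pairwise_coal"] = np.nan
        return out

    def ancestors(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    def mrca(nodes):
        common = set(ancestors(nodes[0]))
        for nd in nodes[1:]:
            common &= set(ancestors(nd))
        return max(common, key=lambda n: depths[n])

    leaves = [leaf_by_label[t] for t in clone_tips]
    out["mrca_age"] = tip_depth - depths[mrca(leaves)]
    ages = []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            ages.append(tip_depth - depths[mrca([leaves[i], leaves[j]])])
    out["mean_pairwise_coal"] = float(np.mean(ages))
    return out


@dataclass
class CloneTrajectoryPosterior:
    """Accepted rejection-ABC draws over (onset time, selection coefficient)."""

    samples: pd.DataFrame  # columns: t0, s, distance
    tolerance: float
    prior_spec: dict
    n_sims: int

    @property
    def acceptance_fraction(self) -> float:
        return len(self.samples) / self.n_sims

    def interval(self, param: str, ci: float = 0.90) -> tuple[float, float]:
        lo = (1 - ci) / 2
        return (float(self.samples[param].quantile(lo)),
                float(self.samples[param].quantile(1 - lo)))


def _simulate_summaries(t0: int, s: float, N, generations: int, n_sample: int,
                        rng, generation_time_days: float) -> dict | None:
    params = WfParams(population_size_trajectory=N, selection_coefficient=s,
                      onset_generation=int(t0), generations_total=generations)
    freq = wf_simulate(params, seed=rng)
    p_final = freq[-1]
    k = rng.binomial(n_sample, p_final)
    out = {"tip_fraction": k / n_sample}
    Narr = params.n_at()
    clone_sizes = freq[1:] * Narr
    if k >= 2:
        coal = sample_clone_coalescent(clone_sizes, k, seed=rng,
                                       generation_time_days=generation_time_days)
        out.update(coal)
    else:
        out.update({"mrca_age": 0.0, "mean_pairwise_coal": np.nan})
    return out


def abc_infer(observed_summaries: dict, priors: dict, n_sims: int = 2000,
              tolerance_quantile: float = 0.05,
              population_size: int | Sequence[int] = 10000,
              generations: int = 200, n_sample: int = 50,
              generation_time_days: float = 1.0,
              seed=0) -> CloneTrajectoryPosterior:
    """Rejection ABC for clone onset generation t0 and selection s.

    Draws (t0, s) from uniform priors (``priors = {"t0": (lo, hi),
    "s": (lo, hi)}``), forward-simulates the Wright-Fisher clone with a
    backward coalescent sample of its tips, and keeps the draws within
    the ``tolerance_quantile`` of Euclidean distance on summaries
    standardized by their simulation spread.  Summaries used are the
    sampled clone tip fraction, clone MRCA age, and mean within-clone
    pairwise coalescent time (the last two skipped when unavailable).
    """
    rng = as_rng(seed)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    lo_t, hi_t = priors["t0"]
    lo_s, hi_s = priors["s"]
    draws, sums = [], []
    for _ in range(n_sims):
        t0 = int(rng.integers(lo_t, hi_t + 1))
        s = float(rng.uniform(lo_s, hi_s))
        sm = _simulate_summaries(t0, s, population_size, generations, n_sample,
                                 rng, generation_time_days)
        draws.append((t0, s))
        sums.append(sm)
    keys = [k for k in ("tip_fraction", "mrca_age", "mean_pairwise_coal")
            if k in observed_summaries and np.isfinite(observed_summaries[k])]
    S = np.array([[sm.get(k, np.nan) for k in keys] for sm in sums], dtype=float)
    obs = np.array([observed_summaries[k] for k in keys], dtype=float)
    scale = np.nanstd(S, axis=0)
    scale[scale == 0] = 1.0
    Z = (S - obs) / scale
    # missing simulated summaries (extinct clones) get a large penalty
    Z = np.nan_to_num(Z, nan=10.0)
    dist = np.sqrt((Z ** 2).sum(axis=1))
    tol = float(np.quantile(dist, tolerance_quantile))
    keep = dist <= tol
    if not keep.any():
        raise ValueError("no acceptances; increase tolerance_quantile or n_sims")
    df = pd.DataFrame(draws, columns=["t0", "s"])
    df["distance"] = dist
    return CloneTrajectoryPosterior(samples=df[keep].reset_index(drop=True),
                                    tolerance=tol,
                                    prior_spec={"t0": (lo_t, hi_t), "s": (lo_s, hi_s)},
                                    n_sims=n_sims)
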