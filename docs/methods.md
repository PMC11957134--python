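# Methods

This note documents the models behind each stage of clonescope, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic data do and do not emulate.

## Clone-tree and genotype simulation

Clones arise by serial subcloning from a single founder lineage: the
clone with the longest culture time forms a backbone and every other
clone attaches to it at a time drawn Uniform(0.05, 0.6) × its own culture
span, giving a caterpillar topology whose root-to-tip duration for every
cell equals that cell's culture time. Cells of a clone diverge from each
other `within_clone_days` (default 2 d) before sampling, so both cells
share every clone-private mutation older than that. Mutations accumulate
on each branch as Poisson(`mutations_per_day` × branch days); the truth
genotype of a cell is the union of mutations on its root-to-tip path, so
the truth matrix is perfectly tree-compatible (zero homoplasy).

`invitro_benchmark_design()` fixes the 16-cell benchmark: two parental
cells sampled at day 10 plus two cells from each of seven subclones at
weekly intervals (days 25–67). The culture durations are free parameters
of the simulator; these defaults span several weeks so that the
branch-length/time correlation is identifiable at desk scale.
`mutations_per_day` defaults to 4, giving ~40–280 observed-scale
mutations per tip path; real PTA genomes carry ~15k somatic SNVs per
cell, but every downstream statistic used here (Spearman correlation,
RF distance, bootstrap support, AUC) depends on relative, not absolute,
mutation counts.

A consequence of Poisson branch counts: a backbone segment that happens
to receive zero mutations is invisible to any reconstruction method, so
"RF distance 0 to truth on noiseless data" holds exactly only for trees
whose internal edges all carry ≥ 1 mutation. Tests assert RF = 0 on
fully identifiable matrices and RF ≤ 2 × (number of zero-mutation
internal edges) on simulated ones.

## WGA read-count model

Allelic dropout is defined per allele: each allele of a het site fails
to amplify independently with probability q. Conditional on retained
coverage, the fraction of het sites showing a single allele — the
locus-level ADO the estimator reports — is 2q/(1+q), so the generator
inverts q = a/(2−a) to hit a target locus-level rate a. Chemistry
profiles bundle four parameters:

| parameter | PTA-like | MDA-like | meaning |
|---|---|---|---|
| `ado_rate` | 0.057 | 0.164 | locus-level allelic dropout |
| `imbalance_dispersion` | 0.08 | 0.45 | allele fraction ~ Beta(c, c), c = 1/dispersion |
| `amp_error_rate` | 1e-3 | 2e-3 | per-read allele flip probability |
| `mean_depth` | 30 | 30 | Poisson depth per site |

Amplification errors flip reads to the other allele, which produces the
characteristic low-BAF false-heterozygous calls the QC stage measures.
Hemizygous deletions set the lost haplotype's depth to this error
background only, with a per-site phase drawn once so all carrier cells
lose the same allele. The generator does not emulate read-level
artifacts (chimeras, coverage waves, GC bias, mappability), so passing
tests demonstrate estimator correctness under the stated statistical
model, not robustness to every real-data failure mode.

## Consensus and somatic calling

UMI families below `minmem` = 3 reads are rejected; per position a base
is emitted when its fraction is ≥ 0.8 (ties emitted), else `N`; a
consensus with more than 30% `N` is discarded. The somatic test is a
one-sided Fisher's exact test for tumor alt enrichment (the direction a
somatic call asserts) at threshold p < 1e-4, plus a germline filter
(normal alt reads < 5, read interpretation: variant-supporting reads —
a total-depth reading would discard nearly all sites) and a strand
filter (≤ 90% of tumor alt reads on one strand). Only a single-strand
consensus pass is implemented; duplex (strand-aware) consensus is not.

## QC estimators

ADO: fraction of het sites with total depth ≥ `min_depth` (default 5)
showing exactly one allele. Error reads can rescue a dropped allele at
~3% of sites at default depth, biasing the estimate down by ~0.002 —
inside the ±0.01 recovery tolerance. Recall: fraction of germline het
sites whose variant allele survives the somatic-path filtering.
Linked-read precision: a candidate sSNV is assessable when ≥ 4 spanning
reads cover it together with a het SNP and both het alleles are seen;
a (het allele, sSNV allele) combination is real only on ≥ 2 reads
(guards against lone sequencing errors); the candidate is supported when
its alt allele pairs with exactly one het allele. Burden correction
subtracts the mean normal-cell call count and divides by a configurable
callable genome size (default 2,800 Mb).

## Mirrored-BAF CNV calling

Per qualifying SNP (depth ≥ 8), mirrored BAF = max(BAF, 1−BAF); windows
(default 5 kb, 0-based half-open, tiling from coordinate 0) need ≥ 3
such SNPs per cell to pass QC. The ROC counts an imbalance call in a
carrier-clone cell as a true positive and in a non-carrier cell as a
false positive, sweeping thresholds over [0.5, 1]; both rates are
monotone in the threshold, so the AUC integrates the curve in threshold
order with (0,0) and (1,1) endpoints. Uncertainty is mean ± 2 sd over
100 bootstrap resamples of cells. Balanced windows average ~0.62 at 30×
(binomial + beta noise folded upward), deleted windows ~1.0, which is
what drives AUC ≈ 1 at PTA-like dropout.

## Phylogeny reconstruction

Distances are mutation-count differences over co-genotyped sites scaled
by the inverse co-coverage fraction (pairwise deletion; missing entries
are uninformative, never treated as reference). Neighbor-joining uses
scikit-bio's array-based implementation (deterministic under ties);
negative NJ branch lengths are clamped to 0. Trees are rooted on a
supplied outgroup or an all-reference pseudo-cell that is pruned after
rooting. An exhaustive Fitch-parsimony search (≤ 8 cells) provides an
independent method for cross-checks. Bootstrap supports come from
resampling variant columns with replacement and counting clade recovery.

## Time calibration

Branch mutation counts are modeled m_b ~ Poisson(λ t_b) with a
Gamma(0.01, 0.01) prior on λ (weakly informative; it does not set the
time scale) and flat priors on durations, giving conjugate Gibbs
conditionals λ | t ~ Gamma(a₀+Σm, b₀+Σt) and t_b | λ ~ Gamma(m_b+1, λ).
Anchors (known or interval-prior root-to-tip ages, e.g. premalignant
cells whose divergence is placed in the first year of life under the
embryonic-HSC assumption) are enforced after each draw by multiplicative
rescaling of the branches on each anchored path, cycled 10 times so all
path-sum constraints hold jointly. For a single anchored chain this is
exact (the Dirichlet(m+1) conditional of split proportions given a fixed
total); with branches shared across anchored paths it is an iterative
projection and therefore approximate. On the 16-cell benchmark the
posterior rate mean lands within ~3% of the generating clock.

## Skyline

The classic generalized skyline: an interval with k lineages and width w
ending in a coalescence estimates N̂ = k(k−1)w/2; adjacent intervals are
pooled until each group spans ε, with ε chosen by AICc over a grid using
the exponential composite likelihood of the grouped intervals. Credible
bands come from recomputing the trajectory on posterior time-tree
samples. It replaces full nonparametric Bayesian phylodynamics — a
declared simplification; trends and orders of magnitude, not fine
structure, are the supported output. Polytomies are resolved with
zero-length branches.

## Blomberg's K

K = (MSE₀/MSE) / [(tr V − n/Σ(V⁻¹)) / (n−1)] with V the phylogenetic
variance–covariance (shared root-to-MRCA path lengths), MSE₀ the trait
variance about the GLS phylogenetic mean and MSE its V⁻¹-weighted
counterpart; K ≈ 1 under Brownian motion, < 1 for weak signal. The
p-value is the one-sided fraction of tip-label permutations reaching an
equal or larger K (`n_perm` default 999; (hits+1)/(n+1) correction).

## Wright–Fisher ABC

Forward simulation resamples the clone binomially each generation with
selection-weighted expectation p′ = p(1+s)/(1+ps), seeding at 1/N(t₀)
(overridable). Summaries — sampled clone tip fraction, clone MRCA age,
mean within-clone pairwise coalescent time — are computed on observed
trees exactly and on simulated trajectories via a per-generation
Poisson-merger coalescent on the clone-size trajectory N(t)·p(t).
Rejection ABC standardizes summaries by their simulation spread and
keeps draws inside a distance quantile (default 5%); extinct simulated
clones receive a fixed large distance penalty. Generation time defaults
to 1 day (configurable); these summaries are this package's choice, not
a published set. Coverage of the 90% intervals is checked over
replicates whose truth is drawn from the prior conditioned on clone
survival — the only clones one can ever fit — which preserves credible
interval calibration.

## Signatures

SBS96 categories follow the canonical pyrimidine-centered convention
(substitution class major, 5′ then 3′ flank, A/C/G/T order);
purine-reference variants are reverse-complemented. Fitting is
per-sample NNLS against an L1-normalized catalogue; de novo extraction
is multiplicative-update NMF with the KL objective (Poisson-appropriate
for counts), best of `n_restarts`, signatures L1-normalized and matched
to the catalogue by cosine. Early/late contrasts use per-category
two-proportion z-tests with Benjamini–Hochberg correction (FDR 0.05).
The bundled reference catalogue is synthetic — three constructed shapes
(flat clock-like, CpG C>T, TpC APOBEC-like) for tests and examples; real
analyses should load a measured catalogue TSV.

## Treatment response

Clustering is agglomerative (correlation distance, average linkage by
default) on both axes of the mutation × condition VAF matrix, with
missing VAFs imputed as 0 (below detection); the flat cluster count is a
config choice, not hard-coded. A post-treatment clone is emergent iff
none of its defining variants reach the detection limit (default 0.005
VAF, the error-corrected assay's sensitivity) pre-treatment and none of
its defining CNVs were seen; with n pre-treatment cells sampled, an
emergent clone's frequency is bounded above by the rule of three, 3/n.

## Pipeline and reproducibility

All randomness flows through `numpy.random.Generator`; a run's single
seed fans out to per-stage child seeds through `SeedSequence` spawn keys
fixed per stage, so toggling one stage never shifts another's stream and
reruns are byte-identical. Coordinates are 0-based half-open everywhere;
the VCF boundary (1-based) converts exactly once, in `io`.

## Problem sizes

Defaults throughout are desk-scale choices: 16–32 cells, 2–50k het
SNPs, 60–70 five-kb windows, WF populations of 10³–10⁴ over 100–200
generations, 400–3000 ABC simulations, 100 bootstrap/permutation
replicates. Each benchmark in `scripts/acceptance.py` averages 10 seeds.

## Known limitations

- The caterpillar clone topology is one plausible serial-subcloning
  design, not an inference about any particular experiment.
- Multi-anchor time calibration is an iterative projection, not an exact
  constrained posterior.
- The clone coalescent used inside ABC approximates multiple mergers per
  generation and pair-age bookkeeping; it is consistent between the
  simulated and fitted sides but is not an exact n-coalescent.
- Read-level artifacts, exome capture bias, and sequencing-machine error
  profiles are out of the generator's scope.
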