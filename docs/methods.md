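# Methods

This note documents the models implemented in `clupeagen`, the defaults
chosen where the design was open, and what the synthetic-data generator
does and does not emulate.

## Sequence handling and haplotypes

Alignments carry named, contiguous, non-overlapping partitions (by default
a 1131 bp coding gene and a 481 bp control-region fragment, 1612 bp
concatenated). Haplotype collapsing merges identical sequences and assigns
ids in order of first appearance, which makes counts reproducible for a
fixed input file. The default ambiguity rule is `strict`: `N` and `-` are
treated as ordinary states, so only character-identical sequences merge.
The alternative `pairwise-ignore` rule skips sites missing in either
sequence; because that relation is not transitive, each sequence is merged
greedily into the first previously seen haplotype it matches, and the
result can depend on input order — `strict` is therefore the default.

## Pairwise ML distances under GTR+I+Γ

The distance between two sequences is the branch length t maximising the
likelihood of the 4×4 site-pattern count matrix (pairwise deletion of
N/−) under a fixed reversible rate matrix. Rate heterogeneity uses k
equal-probability discrete-gamma categories (category means, not medians;
k = 4 by default) plus a proportion p_inv of invariant sites; variable
categories are rescaled by 1/(1−p_inv) so the full mixture has mean rate
1 and t is in expected substitutions per site. Optimisation is bounded
1-D (Brent on [1e−9, 10]); a maximum at the upper bound raises a
saturation error rather than returning a meaningless distance. With equal
rates and frequencies, one rate category and p_inv = 0 the estimate
reduces to the Jukes–Cantor closed form, which the tests verify to 1e−6.

Substitution-model parameters are inputs; the documented default (equal
exchangeabilities, uniform frequencies, α = 0.5, p_inv = 0.4) is a
reproducible stand-in, not an estimate from any particular dataset.

## Trees and group distances

Neighbor joining follows the Saitou–Nei agglomeration with ties broken by
the lowest index pair, and recovers additive matrices exactly. UPGMA uses
average linkage with node height equal to half the linkage distance. The
"basal" distance between two groups is the unweighted mean of all
between-group pairwise distances — equal to twice the UPGMA root height
when only the two groups are present. (For trees with more than two
groups the two readings differ; the mean-distance definition is
implemented.) The net between-group distance subtracts the mean of the two
within-group means and can be negative for unstructured data; a group of
size one has its within-group distance defined as zero with a logged
warning.

## Diversity, mismatch distributions, AMOVA, MDS

Haplotype diversity is h = n(1 − Σp²)/(n − 1) with Nei's sampling
variance; nucleotide diversity is the mean per-site pairwise difference
(frequency-weighted when computed from a haplotype table), with Nei's
approximate no-recombination variance. Mismatch distributions histogram
raw pairwise difference counts under pairwise deletion; pairs with under
50% comparable sites are excluded and the exclusion count logged. A
mismatch peak at k differences over L sites converts to a per-lineage
uncorrected divergence of 100·k/(2L) percent.

AMOVA uses pairwise nucleotide differences as squared Euclidean distances
(the nucleotide-level Φ statistic, not haplotype-frequency F_ST). One- and
two-level designs are implemented with the standard sums-of-squares
decomposition and mean-square coefficient matrices. Negative variance
components are reported as computed. Permutation tests shuffle individuals
among populations (Φ_ST), individuals within groups (Φ_SC) and whole
populations among groups (Φ_CT); P = (b + 1)/(n_perm + 1) including the
observed arrangement, with a default of 10,000 permutations and a
mandatory seed. Pairwise Φ_ST derives per-pair seeds from one parent seed
so results do not depend on pair order.

Ordination is classical Torgerson scaling (double-centering plus
eigendecomposition). Because Φ_ST matrices can contain small negative
entries, those are floored at zero for the MDS input only; raw values are
always reported. If fewer positive eigenvalues than requested axes exist,
fewer axes are returned with a warning.

## Statistical-parsimony networks

The connection limit is the largest step count j whose "parsimony
probability" reaches the chosen confidence (0.95 or 0.99). That
probability is evaluated under a neutral coalescent for a sequence pair:
coalescence time exponential in coalescent units, Poisson mutations per
site, a 4-state symmetric site model for the probability that k hits leave
an observable difference, and the per-site θ estimated from the sample by
Watterson's method. The probability that all j observed differences are
single hits is a ratio of two one-dimensional integrals over the
coalescence time, evaluated by 96-point Gauss–Laguerre quadrature in log
space (a direct adaptive-quadrature evaluation of the same integrals is
used as an independent oracle in the tests). Single-step connections are
always admitted.

Construction is agglomerative: haplotype pairs are processed in order of
increasing difference count and every pair that joins two previously
separate components is connected, so alternative equal-length connections
are retained (loops are kept and their number logged rather than resolved
by further coalescent rules); downstream counting uses the minimum-step
spanning resolution. Edges record total steps and per-partition steps;
multi-step edges can be expanded into chains with inferred (unsampled)
median nodes. Components farther apart than the limit stay disconnected.

Core haplotypes are those reaching a frequency threshold (default 5% of
the sample); satellites attach to the graph-nearest core, ties going to
the more frequent core.

`count_group_mutations` counts the mutational steps leading to haplotypes
observed exclusively in a population group — the mutations inferred to
have arisen in the group since its founding. On the spanning resolution,
an edge is counted when the subtree it leads to contains only
group-exclusive haplotypes. One refinement mirrors the core/satellite
reading of founder expansions: when such a subtree contains a dominant
haplotype (≥ 25% of the group sample by default) with its own satellite
cloud, that haplotype is taken to be the founding state, and the stem path
connecting it to the shared portion of the network is excluded — those
steps record the founder lineage's pre-founding history, not in-group
mutations. Simulations with recorded post-split mutation counts show the
refined count is unbiased in aggregate under severe founder scenarios.

## Clock calibrations and dating

All rates are stored as per-lineage per-site per-year substitution rates;
percent-per-My divergence rates (2× per-lineage) and per-gene mutation
units (rate × gene length) are derived conversions. This avoids the
factor-of-2 and factor-of-L errors invited by mixing unit systems. The
operational coding-gene calibration is 0.75 × 10⁻⁸ /site/yr per lineage
(1.5%/My divergence) over 1131 bp with a 4-year generation interval; a
control-region calibration is derived from it by the modeled-rate ratio
at the interspecies anchor (default 3.6×). Ages print as whole ky and My
to one decimal.

The direct-count age t = n/(μ_gene·N) assumes a star coalescence and no
drift or migration since founding; post-founding coalescence among the
sampled lineages only removes observable mutations, so it is a minimum
estimate. Isolation-with-migration split times arrive in per-gene mutation
units and convert linearly; TMRCA from a basal divergence d% is
d / (divergence rate). The time-dependent-rate comparison is implemented
as paired reports of coding-gene- versus control-region-based ages for the
same events, not as a model of rate decay.

## The coalescent simulator

A single non-recombining haploid locus (mtDNA; all sizes are effective
female numbers) is simulated backward in time under a two-deme
isolation-with-migration demography: an ancestral population of constant
size N_anc splits (forward in time) into two demes with founder sizes
s₁·N_anc and s₂·N_anc; each deme grows exponentially at rate g from its
founder size until it reaches a carrying size, then stays constant;
lineages migrate backward at per-generation rates m₁₂, m₂₁. Waiting times
are drawn by exact piecewise-analytic inversion of the integrated
coalescence hazard — there is no time discretisation, and for a constant
population the pair TMRCA has its exact exponential distribution with
mean N generations (verified against closed forms and against an
independent coalescent implementation, msprime, in the tests).

Mutations fall as a Poisson process per partition (defaults: coding gene
at 3 × 10⁻⁸ /site/generation, control region 3.6× faster over 481 bp).
Infinite-sites mode (default) assigns each mutation a fresh site so truth
accounting is exact; finite-sites mode draws sites uniformly and evolves
bases by the substitution model's jump chain, allowing homoplasy. The
truth record stores the genealogy (Newick, branch lengths in
generations), the true split time, per-branch mutation counts per
partition, and per-deme counts of post-split exclusive mutations —
mutations younger than the split on branches whose descendant samples all
belong to one deme, i.e. exactly what the direct-count estimator and the
network mutation count try to recover.

### Scenario defaults

The `transarctic_bottleneck` preset encodes the study conditions: an
ancestral deme of N_anc = 150,000 (chosen so that per-site diversity is
≈ 0.9%, the magnitude observed in large oceanic herring samples given the
coding-gene clock), a split 10,000 years (2,500 generations) before
present — the Holocene window implicated for the invasion — and founder
fractions of 99% (remaining ancestral deme) and 1% (founding deme), the
founding share inferred for the European groups. The founding deme
recovers at g = 0.005 per generation toward a large carrying size
(500,000): the slow recovery keeps the founder effect visible as reduced
haplotype diversity, while the large recent size keeps the post-split
genealogy star-like — the two signatures the system shows (dominant
cores with satellite clouds, strongly reduced h). `balsfjord_serial` uses
a 0.05% founder fraction, the share inferred for the most extreme
serially-founded population. Migration defaults to zero in both; an
island-model preset with symmetric migration is provided for
structure-statistic checks.

In the parameter-recovery experiment the direct-count estimator pools the
mutation counts of both partitions and uses the corresponding pooled
calibration over 1612 bp: the estimator is count-limited at Holocene ages
and desk-scale sample sizes, and pooling roughly doubles the counts
without changing the expectation. With 50 sampled founders the median
recovered age over 100 replicates sits within about 15% of the true split
(a mild underestimate, as expected for a minimum estimator whose
post-split coalescences hide mutations).

### What the generator does not emulate

Selection, recombination, multiple loci, serial sampling in time,
sequencing error and alignment gaps are absent; real control regions also
violate the homogeneous-rate Poisson model through hotspots. Passing the
simulation-based tests therefore demonstrates internal consistency of the
estimators under the assumed neutral demography, not robustness to these
real-data features.

## Numerical and degenerate-input choices

* Pairwise ML distances: saturation bound 10 substitutions/site; pairs
  with no comparable sites raise errors rather than returning defaults.
* NJ/UPGMA ties: lowest-index pair joined first; tiny negative NJ branch
  lengths (|x| < 1e−12) are clamped to zero.
* Permutation P-values never reach zero by construction.
* The parsimony-probability integrand is evaluated in log space to avoid
  underflow at sequence lengths in the thousands.
* The simulator caps total time at 10⁹ generations as a non-coalescence
  safeguard.
* Network invariance: input order of equally frequent haplotypes does not
  change the network up to isomorphism (ordering inside a difference
  level only affects which of several retained alternatives is listed
  first).

## Known limitations

* The pairwise-ignore ambiguity rule is order-dependent (documented
  above); use strict collapsing for publication-grade counts.
* Two-level AMOVA assumes every population belongs to exactly one group.
* The TCS loop-resolution heuristics (coalescent criteria for breaking
  ambiguous connections) are intentionally not implemented; loops are
  retained and the minimum-step resolution is used for counting.
* The network mutation count cannot distinguish in-group mutations from
  pre-founding private variation when a founder lineage's haplotype was
  not re-sampled in the source deme; the core-stem exclusion corrects the
  dominant-core case but rare secondary founder lineages can still
  contribute a small overcount.
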