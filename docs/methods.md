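# Methods

`phylosowh` implements a complete desk-scale pipeline for multilocus
phylogenetics of the kind used to interrogate poorly supported deep nodes
("troubled backbones") in large supermatrices: curation of per-locus
alignments into a filtered supermatrix, partitioned maximum-likelihood (ML)
inference under GTR+Γ+I, nonparametric bootstrap support, gene-tree conflict
scanning, and the Swofford–Olsen–Waddell–Hillis (SOWH) parametric-bootstrap
topology test.  A synthetic-data generator with a known true tree stands in
for real sequence data, so every stage can be validated against ground truth.

## Supermatrix curation

Per-locus alignments are concatenated over the union of isolate ids; an
isolate absent from a locus is padded with `?`.  Isolate ids are joined by
exact string match only — no fuzzy species-name matching — because merging
sequences from different vouchers under one name ("mixed accessions") is a
known source of spurious signal in multilocus studies.

Column occupancy (completeness) is the fraction of isolates with a
determined character in a column.  `-`, `?`, `N` and `X` count as missing;
all other IUPAC ambiguity codes count as present, since the filter targets
unalignable intron gap regions, not polymorphic base calls.  The filter
retains a column iff its presence fraction is **≥ cutoff** (default 0.10),
i.e. columns with *strictly more than* 90 % missing data are excluded; a
column at exactly the boundary stays.  The filter is idempotent, never
rewrites retained characters, and is applied to the full matrix (including
any outgroup-only columns).  Protein-coding locus partitions can be split
into codon-position partitions by `(within-locus index − frame) mod 3`;
within-locus coordinates come from the concatenation bookkeeping, so columns
removed earlier do not shift the reading frame, and gap columns keep their
positional codon class.  Partition schemes are read and written in the
RAxML `DNA, name = 1-500\3` dialect with 1-based closed intervals.

## Likelihood model

Each partition evolves under GTR: `Q_ij = r_ij π_j` (i ≠ j), with the
exchangeability `r_GT` pinned to 1 and `Q` normalised so the expected number
of substitutions per unit branch length is 1 at the mean site rate.
Rate heterogeneity combines a discrete gamma (k = 4 equal-probability
categories represented by their **means**, the convention of the standard ML
tools) with an invariant-sites class: a site is invariant (rate 0) with
probability `p_inv`, else in category c with probability `(1 − p_inv)/k`.
Gamma category rates are divided by `1 − p_inv` so the mixture's mean rate
stays 1 and branch lengths remain in expected-substitutions units.
`p_inv` is capped at 0.99 for identifiability.

Partitions share one branch-length set ("linked branch lengths") scaled by
per-partition rate multipliers `m_p > 0` whose length-weighted mean is held
at 1; renormalisation after optimisation is compensated exactly by rescaling
the shared branch lengths, leaving the likelihood unchanged.

The log-likelihood is computed by Felsenstein's pruning algorithm.  Gaps,
`?`, `N` and ambiguity codes enter as partial-likelihood vectors with ones
in every compatible state.  `P(t)` comes from an eigendecomposition of the
symmetrised rate matrix (exact for reversible models).  Two implementations
exist and are cross-checked in the tests: a NumPy reference with per-node
underflow rescaling, and numba kernels without rescaling used by tree
search — at the tree sizes this package targets (≲ 80 taxa) site
likelihoods stay far above the double-precision floor, and the kernels
return a sentinel (treated as arbitrarily bad) if a site likelihood ever
underflows.

Site patterns are compressed per partition (`numpy.unique` over columns)
with integer weights; compression is exactly likelihood-preserving.

## Optimisation

Branch lengths are optimised by safeguarded Newton steps on each edge using
above/below partial vectors, refreshed at the start of each sweep; the best
configuration across sweeps is kept, so the reported lnL never decreases.
Branch lengths are bounded to [1e−8, 10].  Substitution parameters are
fitted by cyclic coordinate descent: bounded Brent on each exchangeability
(log scale, [1e−3, 1e3]), each base-frequency coordinate (log scale against
a frozen reference vector, renormalised to the simplex), the gamma shape
(log scale, [0.02, 100]), `p_inv` ([0, 0.99]) and each rate multiplier.
Every accepted move must improve the log-likelihood, so sweeps are monotone;
fitting stops when a full sweep gains less than `tol` (default 1e−4 lnL
units).

Tree search scores topologies under a profile-likelihood scheme: branch
lengths are optimised per candidate topology with the substitution model
held fixed; the model is re-fitted on the incumbent best topology between
scan rounds until the topology stops changing.  Candidate scans use a few
coarse Newton sweeps; the top candidates are then "polished" to tight
convergence before the winner is chosen, with ties (within 1e−9 lnL) broken
by the lexicographically smallest canonical Newick string, making results
deterministic.  Exhaustive enumeration, guarded to ≤ 9 taxa ((2n−5)!!
topologies), gives the global optimum among trees displaying the constraint;
the NNI hill-climb starts from random stepwise-addition trees (or a supplied
warm-start tree) and moves while any neighbour improves lnL.

Backbone constraints use *display* semantics: a possibly multifurcating
constraint tree on a taxon subset is satisfied iff all of its non-trivial
splits appear in the candidate tree after restriction to the constraint's
taxa; polytomies impose nothing.  Constraint-compatible NNI starts are built
by randomly resolving the constraint's polytomies and stepwise-adding the
remaining taxa — neither operation can break a displayed split.

## Bootstrap and conflict scanning

Nonparametric bootstrap resampling is stratified within partitions
(multinomial redraw of pattern weights, preserving partition lengths); each
replicate is re-searched with the model fixed at the full-data fit, and
split frequencies (percent of B) are mapped onto the base tree's internal
edges.  Gene-tree conflict follows the compat-style definition: two splits,
one per tree, each with support at or above a cutoff (default 70) on the
shared taxon set, that are mutually incompatible (no empty pairwise block
intersection).  Trees are restricted to shared taxa first; when restriction
collapses several edges onto one split the highest support is kept.

## SOWH test

The statistic is `δ = lnL(unconstrained ML tree) − lnL(best tree displaying
the constraint)`.  Null replicates are simulated on the **constrained** ML
tree with its own fitted parameters — H0 is the constrained hypothesis —
then both searches are re-run per replicate.  Replicate searches may reuse
the observed fits as warm starts; final lnLs are always fully re-optimised,
so this affects speed only.  By default the observed missing-data footprint
is re-imposed on each simulated alignment (configurable), since ignoring
heavy missingness would inflate the apparent information content of the
nulls.

Three p-values are reported side by side: the raw empirical proportion
`#{δ_r ≥ δ}/n` (SOWHAT-compatible; can be exactly 0 or 1), the add-one
corrected `(#+1)/(n+1)` (never 0), and a one-sided Student-t approximation
with `t* = (δ − mean)/(sd·√(1+1/n))` — the prediction-interval form, since
the observed δ is a new draw rather than a sample mean.  A t-test cannot
produce the exact-zero p-values that raw proportions can, so the headline
decision (reject iff p < α) uses the raw empirical p and the report flags
any disagreement between the two at α.

Sequential stopping: once at least 10 nulls exist, a 95 % Wilson score
interval for the raw p is computed after each replicate; sampling halts when
the interval lies entirely on one side of α (on either side — a decision
that is already settled does not change with more sampling).  The
`percent_ratio` diagnostic reports the fraction of the planned replicate
budget actually sampled.  Note the arithmetic consequence: with zero
exceedances the upper Wilson bound `z²/(n+z²)` crosses α = 0.05 only at
n ≥ 74, so clear rejections stop around 74 replicates, and clear
non-rejections (raw p near 1) stop at the 10-replicate floor.

Likelihood differences smaller than 1e−6 (the branch optimiser's
convergence scale) are snapped to zero before p-values are computed:
an observed δ of +1e−9 of optimiser noise must tie with, not exceed, null
deltas of exactly zero, otherwise a constraint the ML tree itself satisfies
could be "rejected" with raw p = 0.

When the search is exhaustive and the model fixed, one scan of all
topologies supplies both optima (the unconstrained maximum is taken over a
superset including the constrained winner), so δ ≥ 0 holds exactly.  With
heuristic search δ can come out negative when the constrained search happens
to find a better tree — a search artifact, not a property of the test.

## Sequence simulation

Alignments are simulated edge-wise under exactly the likelihood mixture:
per site, an invariant/category assignment is drawn i.i.d. within each
partition; invariant sites keep their root state (drawn from π) along the
whole tree; other sites transition with `P(t·m_p·r_c)` down each edge.
There is no indel process — gaps arise only from the missing-data footprint
applied afterwards.  Two runs with equal seeds are byte-identical.

## Synthetic studies

`synth_study` emulates the statistical shape of an eight-locus fungal
supermatrix at desk scale: a Yule-topology true tree whose branch lengths
are redrawn i.i.d. exponential (mean 0.08) with the most balanced internal
edge pinched to 0.01 — a deliberately troubled backbone; 8 loci, half
protein-coding (lengths made divisible by 3 so codon partitioning applies),
lengths drawn from 200–900 columns by default; per-locus GTR parameters
drawn from moderately informative priors (Dirichlet(8) frequencies,
log-normal exchangeabilities centred on transition-rich values, α ∈ [0.3,
1.5], p_inv ∈ [0, 0.3]); log-normal locus rate multipliers; a long-tailed
missing-locus footprint (per-taxon Beta-distributed missing probability with
mean 0.25, constrained so every taxon keeps ≥ 1 locus and every locus ≥ 4
taxa); and intron-like blocks inserted into non-coding loci in which exactly
one isolate carries (random, non-tree) sequence — occupancy 1/n_taxa, below
the 10 % cutoff whenever n_taxa ≥ 11, so the filter removes exactly those
columns.  The manifest records every true parameter for recovery tests.

What the generator does *not* emulate: alignment error, real indel
structure, paralogy/contamination, codon-level selection, and
between-partition branch-length heterogeneity beyond a scalar multiplier.
Passing tests therefore demonstrate correctness of the algorithms under the
model, not robustness to model violation in real data.

## Problem sizes used in the automated runs

The test suite validates the likelihood engine against brute-force
enumeration on 3–5 taxa, search quality on 6 taxa (105 topologies,
20 simulated datasets), simulator consistency on 4 taxa × 50,000 sites,
parameter recovery on 5,000–10,000 sites, and SOWH calibration with 200
six-taxon tests of 50 null replicates each (JC model, 200 sites, the
constrained split present on a very short internal edge).  The acceptance
script runs the full pipeline on a 12-taxon, 8-locus study (150–400 columns
per locus, 25 % missing blocks, 3 intron blocks), with a 20-replicate
bootstrap and two NNI-based SOWH tests (≤ 40 replicates, sequential
stopping).  These sizes are the package's chosen desk-scale study
conditions; all stages scale to larger inputs through the same interfaces.

## Known limitations

* The numba kernels skip underflow rescaling (sentinel fallback); very large
  trees should use the NumPy reference path.
* Coordinate-descent fitting can need many sweeps when exchangeabilities and
  frequencies are strongly correlated; the defaults favour robustness over
  speed.
* NNI-only rearrangement can be trapped by local optima that SPR/TBR would
  escape; multiple random-addition starts mitigate but do not eliminate
  this.
* The t-approximation to the SOWH null is reported as a diagnostic only; its
  exact form (including the √(1+1/n) factor) is a documented package choice.
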