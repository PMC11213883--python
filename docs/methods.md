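# Methods

`lexiphylo` implements a Bayesian phylogenetic analysis of binary cognate
data of the kind used to study language family history: doculects (documented
language varieties) are rows, cognate sets are binary presence/absence
characters grouped into meanings, and the object of inference is a clocked,
rooted time tree together with the parameters of the lexical replacement
process. This note records the model, the numerical choices, and the places
where the design was genuinely open.

## Data model

A cognate matrix holds states in {absent, present, missing} with
*meaning-level missingness*: a doculect is either coded for all cognate sets
of a meaning or for none of them, reflecting how basic-vocabulary databases
elicit one meaning at a time. Sub-cognate sets (finer codings that track
sound changes inside a primary cognate set) are dropped before analysis, and
doculects attesting fewer than 80 present cognate sets are discarded (the
threshold is strict: "fewer than", so exactly 80 survives). Meanings are
partitioned into bins by their number of cognate sets (widths of 10: 1–10,
11–20, ...); bins enter the likelihood only as relative rate multipliers.

## Substitution model

The binary covarion process has four states ordered (absent/slow,
present/slow, absent/fast, present/fast). Gain/loss within the slow category
runs at a fraction `alpha` of the fast-category rate; the hidden category
toggles at rate `s` without simultaneous observed change. Hidden-state
frequencies are (0.5, 0.5); observed equilibrium frequencies
(`f_absent`, `f_present`) default to (0.992, 0.008) and in practice are set
to the empirical values of the analysed matrix. The generator is normalized
so the expected *observed-state* change rate at stationarity is 1, which
makes clock rates read as expected gains+losses per cognate per year; the
normalizing constant is `2·f0·f1·(alpha·h0 + h1)`, which for hidden
frequencies (0.5, 0.5) reduces to `f0·f1·(alpha + 1)`. The process is
reversible; transition
probabilities come from a symmetrized eigendecomposition, which also lets a
whole batch of branch distances share one decomposition.

## Likelihood and ascertainment

Column likelihoods are computed by Felsenstein pruning over the four
covarion states with tip partials absent → (1,0,1,0), present → (0,1,0,1),
missing → (1,1,1,1) and stationary root weights. Because all-absent cognate
sets can never be observed, each column is conditioned on observability.
The correction is applied per meaning: the all-absent pattern is evaluated
under that meaning's coverage (uncovered doculects are missing, not absent)
and `log(1 − exp(log P(all absent)))` is subtracted from every column of the
meaning. Occasional rescaling during pruning (every 8th internal node)
guards against underflow at a couple of hundred taxa.

Per-cognate log-likelihoods are logged in corrected form — each column
carries its own copy of its meaning's correction — because the topology test
consumes one value per cognate set.

## Priors

* Tree: root-conditioned Yule. Conditional on the root age `T` and birth
  rate `λ`, the `n−2` interior node ages are iid with density
  `λ e^{−λa} / (1 − e^{−λT})` on `(0, T)`; topology uniform over labeled
  histories. This calibrated form was chosen deliberately: it makes the
  prior marginals of the root age and the birth rate exactly their stated
  priors (the count of labeled histories compatible with any age ranking is
  a constant), so prior-sampling validation is exact rather than
  approximate. For `n = 2` the node-age term is identically zero.
* Root age: Normal(5200, 100) years BP.
* Birth rate: LogNormal(−7.5, 2.0); clock mean: LogNormal(−10.0, 2.0) —
  both parameterized by (meanlog, sdlog) of the underlying normal.
* Clock stdev: Gamma(0.5396, 0.3819), read as (shape, scale); a config
  switch (`gamma_is_shape_rate`) exposes the shape/rate reading.
* Branch rates: the relaxed clock uses continuous per-branch multipliers
  with a unit-mean lognormal prior, LogNormal(−σ²/2, σ) with σ the clock
  stdev. A strict clock (σ = 0) pins all multipliers to 1 and contributes a
  point-mass convention of 0 to the log prior.
* Covarion: `alpha` uniform on (0, 1]; `s` LogNormal(−1, 1). These are not
  fixed by the analysis this package re-implements and are the package's
  own defaults.
* Partition-rate multipliers: constrained to a column-count-weighted mean
  of 1 (only relative rates are identifiable next to the clock mean);
  uniform prior on the constraint surface.

## Sampler

Metropolis–Hastings with a conventional time-tree kernel: uniform and
scaling node-age moves, a root scaler, narrow exchange, a no-crossing
subtree slide (a bracketed age move; topology changes are handled by the
exchange and Wilson–Balding kernels), Wilson–Balding re-attachment, scalers
for the scalar parameters, a branch-rate random walk, and a weight-preserving
partition-rate exchange. Three less standard moves matter for mixing:

* *prior-draw independence proposals* for the clock mean, switch rate,
  alpha, clock stdev and birth rate: the Hastings term cancels the prior
  ratio, so acceptance reduces to the likelihood ratio. In prior-only mode
  they are accepted with probability 1, making prior validation essentially
  iid.
* the *stdev rescale* move transforms all branch rates through their
  standardized residuals when the clock stdev changes (a non-centered
  parameterization step), avoiding the funnel between σ and the rates. The
  prior-draw version of the stdev move applies the same transform.
* the *clock–rate exchange* multiplies the clock mean by `m` while dividing
  every branch rate by `m`, walking the likelihood-invariant ridge.
* the *birth-rate prior draw* quantile-maps every interior node age through
  the conditioned-Yule age distribution so that (λ, ages) jump together.

Monophyly constraints (`must_be_clade` / `must_exclude`) are enforced by
rejection after topology moves; the initial tree is a seeded random
resolution that satisfies all constraints (nested constraints are honoured,
overlapping non-nested ones rejected). A "fall outside group X" hypothesis
is expressed as `must_be_clade` on the complement group.

Chains are fully deterministic given (config, seed). Desk-scale defaults are
200k generations sampled every 200; the validation suite uses 14k–30k
generation chains on 9–15 taxa, sizes chosen so the whole suite completes on
one CPU in minutes. Convergence is summarized by the effective sample size
(Geyer initial-positive-sequence truncation; a constant trace reports 0) and
the pipeline refuses to continue to downstream stages below a configurable
ESS threshold (default 200).

## Posterior summaries

Majority-rule consensus includes exactly the clades with frequency strictly
above the threshold (≥ 0.5); ties at the threshold are excluded, which keeps
the rule deterministic and the clade set automatically compatible. The MCC
tree is the sampled tree maximizing the summed log clade frequencies, ties
broken by first occurrence; node heights are re-annotated with the median
clade age over the trees containing that clade (common-ancestor heights are
not used), with a nudge preventing parent–child age inversions that
independent medians can produce. The group-topology census collapses named
disjoint groups to single tips in every tree where all groups are
monophyletic and reports canonical (label-sorted) induced topologies with
frequencies and cumulative mass; trees where any group fails monophyly fall
into an explicit "(incompatible)" bin, so both the conditional and the
unconditional reading are recoverable.

## Innovation reconstruction

For a focal clade, each posterior sample contributes one exact joint draw of
covarion states at every node (inside partials, then root-to-tip stochastic
traceback). A cognate counts as an innovation when the origin node (parent
of the clade's MRCA) is observed-absent (states 0/2) and the MRCA is
observed-present (states 1/3); the innovation posterior probability is the
fraction of samples where the indicator fires. The MRCA is located per
sampled tree whether or not the clade is monophyletic there (the monophyly
fraction is reported alongside); samples where the MRCA is the root are
skipped and counted. Joint sampling (not independent thresholding of the two
marginals) is the implemented semantics; it is the correct reading of "absent
at the origin and present at the MRCA" as a single event.

## Topology test

Two analyses constrained to rival hypotheses log corrected per-cognate
log-likelihoods. For each cognate the 50% HPD interval is computed in both
traces — the HPD is the shortest window whose endpoints are sample values
containing `ceil(mass·N)` samples, ties broken by the smallest lower
endpoint — and cognates with non-overlapping intervals are classified as
supporting whichever analysis puts them strictly higher. HPDs are computed
on log-likelihoods. For presentation, intervals are shifted per cognate by
the median of the first analysis's trace.

## Language-switching analysis

The binary population trait (background vs. 'negrito', the collective label
for Philippine populations descending from pre-Austronesian inhabitants, all
of whom now speak Austronesian languages) is reconstructed by unit-cost
Sankoff parsimony with the root fixed to background — switching is
directional, so reversals are excluded a priori rather than penalized.
Ambiguity at equal-cost nodes keeps the parent's state by default, which
delays switches tipward and yields the latest (most conservative) switching
dates; an "earliest" rule is available. Each transition branch is reported
with the ages of its bookending nodes as (min, max) switching dates. Branch
categories (background / transition / within-negrito) partition the
branches; the per-category *weighted mean rate* uses branch time-durations
as weights, making category means commensurate with per-year rates, and the
comparison statistic is the posterior probability (across sampled trees,
each with its own parsimony reconstruction) that the transition-category
mean exceeds the background mean.

## Synthetic data

The generator emulates the structure of a basic-vocabulary dataset: default
scale is 202 doculects and 185 meanings with a truncated-geometric number of
cognate sets per meaning (mean 41 ≈ 7565/185), root age 5200 BP, clock mean
e^{−10} ≈ 4.5·10⁻⁵ changes per cognate per year, covarion equilibrium
present-frequency 0.008, and 10% meaning-level missingness. Columns evolve
from a stationary root draw and are redrawn until observable (not all-absent
among covered doculects), mirroring ascertainment. Ground-truth node states
are retained per column, so tests can replay the matrix exactly and can
distinguish injected from naturally-arising innovations.

Injected innovations set a column present exactly in a designated clade with
the gain recorded on the stem. Borrowing is modeled as discrete copy events:
at an event time, every cognate carried by the donor lineage (per the
ground-truth state at the donor-side node of the spanning branch) is copied
into the recipient lineage with a stated probability and inherited by its
descendant tips; every copied cell is logged. Note the donor's carried set
is read at the node below the event time, a deliberate simplification of
within-branch state.

What the generator does *not* emulate: dialect-chain (linkage) structure,
sound-change sub-cognates, semantic shift, or geographically structured
borrowing networks. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness of the original
study's conclusions to model misspecification.

## Validation design choices

* Likelihood and ancestral-state machinery are checked against exhaustive
  enumeration on ≤ 6 taxa; the enumeration code lives in the test suite and
  shares nothing with the pruning implementation.
* Prior recovery uses 5000 samples thinned every 60 generations, at which
  spacing every scalar parameter's prior-draw move has almost surely fired
  between samples, so the iid assumption of the KS test holds.
* Parameter recovery infers under the generating equilibrium frequencies
  (the convention of fixing frequencies empirically is applied at the
  generating values, since the small-sample empirical present fraction is
  inflated by ascertainment conditioning relative to the equilibrium).
* Innovation recovery uses a paired design: the injected stem innovation is
  compared against a prevalence-matched control column whose present cells
  are not clade-aligned. Background columns are not valid controls — under
  the generative model some of them genuinely are stem innovations.
* The topology-test experiment evaluates per-cognate likelihood traces over
  age-jittered tree samples from each rival hypothesis, which isolates the
  classification machinery from MCMC noise.

## Known limitations

* The sampler recomputes the full likelihood per proposal (no partial
  caching); fine at validation scale, slow at 202 taxa × 7565 cognates with
  long chains.
* The no-crossing subtree slide is an age move only; topology mixing relies
  on narrow exchange and Wilson–Balding.
* `combine_runs` requires identical model signatures and does not attempt
  cross-run rescaling or reweighting.
* Consensus node ages are independent per-clade medians and can need the
  anti-inversion nudge; they are summaries, not joint estimates.
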