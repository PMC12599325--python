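# Methods

This note documents the models, conventions and numerical choices behind
`coculture`, in the order the pipeline applies them.

## Data model and detection floor

All analyses start from a long-format culture table: one row per replicate
endpoint fluorescent cell density (cells/ml) for a (focal, partner,
environment) culture, with an empty partner marking mono-cultures.  An
environment is a set of carbon sources with a fixed total concentration
(default 1.0 mg/ml) split equally between them; zero sources encodes the
no-carbon control.

Densities below the detection floor (default 4.57×10⁵ cells/ml, the
published constant derived from the 90th percentile of densities observed
without a carbon source) are raised to the floor **per replicate
measurement, before any summary**.  Flooring first means every downstream
ratio and logarithm is finite; it also means constant floored triplicates
occur, which several procedures must handle explicitly (below).  Densities
are stored linear; logs are taken on demand — base 2 for effect sizes,
base 10 for the mixing analysis — matching each formula's natural scale.

## Unidirectional calls and the six classes

The replicate ratios of co-culture density to the mono-culture mean are
tested against 1 with a one-sample two-tailed Student t-test on the **raw**
ratios (not log ratios).  A zero-variance sample makes the t statistic
degenerate; the convention here is p = 1 when the constant mean equals 1
and p = 0 otherwise — needed because floored triplicates can be exactly
constant, and chosen so that "all cultures at the floor" yields unaffected
calls and "co-culture pinned at the floor under a grown mono-culture"
yields a maximally confident call.

The Benjamini–Hochberg family is **every unidirectional test in the run**
(both directions, all pairs, all environments).  A per-environment family
would change only borderline calls; the single global family matches the
one-shot correction of a typical R workflow and is the simplest
defensible choice.  Calls are + / − only when the BH-adjusted q is below
the configured FDR (default 0.05) and the mean ratio lies on the
corresponding side of 1.

Class aggregates used in summaries: synergistic = mutualism +
commensalism; competitive = competition + amensalism; exploitation and
neutralism are reported separately.

## Effect sizes and the interaction-type angle

E is the log2 ratio of mean co-culture to mean mono-culture density; θ is
the angle between the plotted (min E, max E) point and the anti-diagonal
max = −min.  The defining formula is undefined when the two effects are
exactly equal and nonzero (denominator zero); the implementation uses the
continuity limit sign(E_ij+E_ji)·90° and flags such records
(`equal_nonzero` column).  When all four underlying means sit at the
detection floor θ is set to 0° (`at_floor` flag): nothing grew, so no
interaction is claimable.  θ is verified in the tests against an
independent rotated-coordinates oracle (rotate the point by −45°, take the
two-argument arctangent) to 10⁻⁹ degrees.

Because E uses means of floored replicates while the +/0/− calls use a
replicate-level test, the two can disagree in noisy data; both are
reported without forced reconciliation.  The environment average θ̄_m runs
over all pairs present in the environment; the pair average θ̄^{i,j} is
defined only over the single-carbon-source environments.

## Mixing analysis

Group 1 is the observed triple of log10 yields in a mixture; Group 2 is
the three-point pseudo-sample {m̄+s, m̄, m̄−s} built from the component
environments' mean log10 yields and unbiased log10 variances.  The triple
encodes the target mean and unbiased standard deviation *exactly* (an
identity asserted to machine precision in the tests), so it is used
literally rather than through an analytic substitute.  The two samples are
compared with a two-tailed two-sample t-test — Welch's unequal-variance
form by default, the default of common statistical environments; Student's
pooled form is available via `welch: false` and the choice is recorded in
the manifest.  BH correction runs across all (species, mixture)
comparisons of the run.  The headline quantity per mixture size is the
"matched or exceeded" fraction: higher + not-different verdicts.

## Grower stratification

Per species, mono-culture mean log10 yields across the 32 environments are
bimodal: substantial growth versus the detection floor.  The
grower/non-grower split is the two-cluster partition minimising Ward's
criterion (total within-cluster sum of squares).  For 1-D data the global
optimum is contiguous in sorted order, so it is computed **exactly** by an
O(n) prefix-sum scan over the n−1 contiguous splits.  Greedy agglomerative
Ward linkage is deliberately not used: its top-level split differs from
the exact optimum on a substantial fraction of random 1-D instances
(verified against brute force during development), and with only 32 points
per species exactness is free.  Guards: all values at the floor skip
clustering (all non-growers); when the two cluster means are closer than
0.5 log10 units the data are treated as unimodal and labelled as one group
by comparing the grand mean against floor + 0.5 — half an order of
magnitude above the floor is the smallest difference we consider
biologically meaningful growth.  Clustering runs per species across its
environments by default; the per-environment axis is available via
`cluster_axis` for sensitivity analysis.

Interactions are assigned to the `both_growers` stratum iff both species
are growers in that environment.  Class enrichment per (stratum, class)
uses a one-sided hypergeometric over-representation test against the
pooled table, restricted by default to environments with 1, 2 or 4
sources (the bins where both strata are populated), BH-corrected across
all (stratum, class) tests.  An optional sensitivity filter drops records
whose mono-culture means sit at the floor, where inhibition is
undetectable by construction.

## Community statistics

* **Monte-Carlo chi-square.**  Null tables are drawn with fixed row totals
  and pooled column probabilities; each simulated table's Pearson
  statistic uses its own fitted margins, exactly as the observed statistic
  does, so the simulated null matches the (r−1)(c−1) reference.  The
  add-one estimator (1+k)/(1+N) avoids zero p-values, so p is bounded
  below by the resolution floor 1/(1+N).
* **Pairwise PERMANOVA.**  Environments are points in the 28-dimensional
  space of per-pair θ values (Euclidean distance); the pseudo-F compares
  between- to within-category dispersion.  For two categories the label
  assignments are enumerated exhaustively whenever their number is
  manageable, making the permutation p exact; otherwise labels are
  permuted Monte Carlo with the add-one estimator.  The single-member
  "nucleic acids" category (uridine) is skipped with a warning — a
  one-environment group has no within-group dispersion.
* **Species rank enrichment.**  All pairs are ranked by θ (mid-ranks for
  ties); the statistic per species is the mean rank of its pairs, compared
  two-sidedly against random same-size pair subsets (exact enumeration
  when feasible).  This mean-rank permutation test is a deliberately
  simple, fully specified stand-in for gene-set-style enrichment machinery.
* **Spearman trend** between source number and θ uses mid-ranks and the
  two-sided t approximation; constant input is reported as missing.

One master seed drives every stochastic procedure; each derives a stable
sub-seed by hashing its identity, so results are independent of the order
in which analyses run.

## FBA by-product counting

Flux balance analysis maximises the biomass flux of a stoichiometric model
at steady state (linear program solved by cobrapy/GLPK).  The optimal
objective value is unique but the flux vector usually is not, so the
by-product rule never depends on a particular solution: a reaction is
*essential for the optimum* iff forcing its flux to zero lowers the
re-optimised biomass by more than the threshold (default 1%), a property
of optimal values only.  Possible carbon-containing by-products are the
metabolites with ≥1 carbon atom participating in reactions that are both
essential and carry nonzero flux (relative tolerance 10⁻⁹ × max |flux|,
because LP solvers return near-zero noise).  The supplied carbon source
and the biomass pseudo-metabolite are excluded — counting the input as its
own by-product would be a bookkeeping artefact.  Genome-scale models load
from SBML (carbon counts parsed from formulae); all shipped fixtures are
hand-enumerable toy models of ≤ 20 reactions.

## Synthetic data: what it emulates and what it does not

**Planted-effect tables** place known log2 effects on chosen mono-culture
means with lognormal replicate noise (additive Gaussian on log10, matching
the log10 framing of the replicate-variability analysis).  The default
design draws each unidirectional effect uniformly from {0, ±1, ±1.5} with
noise σ = 0.05 log10 over 100 pair-environments — magnitudes that small
endpoint screens can realistically resolve with triplicates, and at which
the t-test's recovery is high but not saturated.

**The consumer-resource simulator** is a discrete-time batch model
(default step 0.05 h over 72 h): each species demands uptake × density ×
dt of every resource it can use; over-subscribed resources are shared pro
rata to demand; consumed carbon splits between biomass (yield 5×10⁸
cells/mg on the assimilated fraction) and a shared by-product pool (30%
re-secretion) that any species may consume, closing the carbon mass
balance to 10⁻⁹ relative at every step.  The discrete-time form avoids ODE
stiffness while keeping closed-form checks (full-consumption yield,
symmetric splitting between identical competitors) exact.  The default
community gives each of 8 species a random 4–6 of the 16 sources at
~10⁻⁹ mg/cell/h (≈0.35/h effective growth), inocula of 10⁵ cells/ml mono
and 5×10⁴ + 5×10⁴ co, and the standard 32-environment design (16 singles,
nested random mixtures of 2/4/8/16, one control).

The mechanism produces the intended phenomenology: in single-source media
most species sit at the floor and the occasional grower cross-feeds its
partner (facilitation, θ > 0), while diverse media let every species grow
and contest the fixed carbon budget (mutual inhibition, θ < 0) — hence a
rising grower fraction and a negative θ–diversity trend.  What it does
**not** emulate: toxin- or pH-mediated inhibition, quorum sensing, spatial
structure, lag phases, plasmid cost, or any fitted correspondence to a
real dataset.  Passing tests on simulated data therefore validate the
statistical chain and the qualitative resource-competition mechanism, not
quantitative agreement with any particular experiment.

## Degenerate inputs and tie-breaking

* Constant t-test samples: p ∈ {0, 1} as above (both one- and two-sample).
* θ with equal nonzero effects: ±90° continuity limit, flagged.
* Ward split ties: the first minimising contiguous cut in sorted order.
* Hypergeometric tests with degenerate margins: p = 1.
* Spearman with constant input: missing, skipped from BH.
* Mixture comparisons with missing component environments: skipped with a
  recorded reason, excluded from the BH family.

## Problem sizes and runtime

The shipped study sizes are the native design (8 species, 28 pairs, 32
environments, triplicates = 896 interactions; 6 144 table rows), simulated
in a few seconds.  Default iteration counts — 10⁵ chi-square draws, 10⁴
PERMANOVA permutations and 10⁴ enrichment permutations — put Monte-Carlo
standard errors well below the decision thresholds at ~10 s total; exact
enumeration replaces sampling automatically wherever the permutation space
is small enough.

## Known limitations

* The simulator is an engineered stand-in; its parameters are not fitted
  to any experimental dataset, and quantitative class proportions differ
  from real screens (in particular, weak effects under triplicate noise
  are conservatively called neutral).
* The BH family choices (global for calls, global for mixing) are
  documented conventions, not derivable facts; borderline calls can shift
  under per-environment families.
* PERMANOVA's feature space (per-pair θ, Euclidean) and the mean-rank
  enrichment statistic are specified here as reasonable defaults; other
  response matrices are accepted via the library API.
* The metabolic-distance and phylogenetic-distance analyses of growth
  profiles are out of scope; only a pluggable growth-profile input to the
  correlation utilities is provided.
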