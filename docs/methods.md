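# Methods

## Model

A gene's expression vector over *n* samples is reduced to the rank
statistic "which *s* samples have the largest values".  Two genes are
versions of the same pattern at tolerance *t* when their top-*s* sets
overlap in at least `s − t` samples; since both sets have size *s*, the
overlap deficit equals `|A \ B| = |B \ A|` and is half the symmetric
difference.  A gene set at a grid cell (s, t) is a connected component of
the match graph (components, not cliques: a set is allowed to drift
through chains of near-identical genes, which matches the smooth
variation of detected sets across neighbouring cells).  Only
up-regulation (top-*s*) is matched by default; a `direction` switch
enumerates bottom-*s* or both.

Ties in expression are broken by ascending sample index everywhere, which
makes every top-*s* set a prefix of one fixed permutation per gene:
results are deterministic and top sets are nested in *s*.

## Grid, saturation and the sentinel stop rule

*s* runs from `s_margin` (default 6; 10 is the common alternative) to
`n − s_margin`.  For fixed *s*, small *t* yields no components of size ≥ 6
on noise, while large *t* merges everything into one giant component, so
*t* needs a per-s ceiling.  Two rules are provided:

- fallback cap `⌊s/2⌋` (consistent with the t ≈ s/5 cells at which real
  sets are typically reported);
- a sentinel stop rule: scan t upward from 0 and stop just before the
  first cell where one component contains at least `majority_fraction`
  (default 0.5) of the sentinel probes *and* at least one foil probe.
  Sentinel/foil lists are explicit config inputs; absent probes are a
  hard error.  Because edges only accumulate with *t* (components merge,
  never split), the first merge is final and the scan can stop there.

The minimum reported component size is 6.  Candidate pruning uses the
sample→probes inverted index: the G×G overlap-count matrix is one sparse
product of the membership matrix with its transpose, thresholded at
`s − t`; a naive all-pairs matcher is kept solely as a test oracle and
both are verified to produce identical components on randomized inputs.
The spiral search (coarse steps, unit-step refinement around hits) is a
reconnaissance device; the enumeration itself is exhaustive.

## Consolidation

Instances are linked by single-linkage on probe-set Jaccard similarity
(threshold 0.5, config-exposed) across all cells — linkage is on gene
membership only, not on the induced sample sets, since versions of one
set at different *s* necessarily carry different-sized sample sets.  The
core of a family is the probes present in at least
`ceil(core_fraction · n_instances)` instances (default half).  A family
whose core probes all map to one gene symbol is flagged as a likely
chip-design artifact (multi-probe genes legitimately co-cluster, but a
set made of *only* one gene's probes carries no co-regulation signal);
an unannotated probe counts as a distinct symbol.  Representative
samples are the majority consensus of the member instances' consensus
sample sets, at the median member size.  Cross-dataset comparison maps
cores to gene symbols and aligns families greedily one-to-one on
symbol-level Jaccard ≥ 0.3 (ties by overlap count).

## Consensus sample set

Within a component, the reported partition is the *s* samples with the
highest membership frequency over member top-sets; ties break by total
rank score (sum over members of *s* minus rank position), then ascending
index.  This realises "one partitioning pattern per gene set".

## Imputation

Gene-axis k-nearest-neighbour imputation, k = 10 by default: donors are
probe rows, distances are Euclidean over the coordinates observed in both
rows, normalised per shared coordinate; a missing entry becomes the mean
of the k nearest donors observed at that column.  The implementation
delegates to scikit-learn's `KNNImputer`, whose nan-Euclidean scaling
(total/shared) ranks donors identically to the per-shared-coordinate
normalisation, so imputed values coincide with the brute-force donor
search (verified in tests).  No log-transform or normalisation is applied
anywhere; the matrix is used on the scale provided, and run manifests
record the input checksum.

## Survival evaluation

A core set scores each sample by the unweighted column sum of its probes'
values.  Splits: median (score ≤ median → low; the tie direction is a
documented convention) and quartiles (`⌊n/4⌋` lowest vs `⌊n/4⌋` highest,
boundary ties resolved by ascending sample index).  The log-rank
statistic is the standard two-group form: at each distinct event time,
observed minus expected events in group 1 under the hypergeometric model,
variance `D·(N₁/N)(1−N₁/N)(N−D)/(N−1)`, tied events handled with the
simultaneous risk-set convention; `χ² = (ΣO−E)²/ΣV` referred to
chi-square with 1 df.  The implementation is vectorised (it is called
thousands of times in simulations) and is cross-checked against
lifelines' `logrank_test` in the test suite.

Five results per family: all/median, all/quartiles, ER+/median,
ER+/quartiles, ER−/median.  The ER-negative stratum is never split by
quartiles (too small).  Cohorts with no known ER status get only the two
all-sample results.  Degenerate splits (constant scores, empty groups,
tiny strata) yield NaN results with a note instead of aborting.  Samples
absent from the clinical table are excluded from survival analysis with a
warning; samples with unknown ER remain in the all-samples stratum.

## Synthetic cohorts

Background entries are i.i.d. N(0, noise_sd²).  A planted set shifts a
probe × active-sample block upward by `delta · noise_sd`; active supports
are drawn disjointly by default (the recoverable benchmark), optionally
overlapping.  A fraction of background genes is represented by 2–5 probes
sharing a base profile plus independent probe noise of the same standard
deviation, emulating multi-probe chip design.  Missing entries are
masked uniformly at `missing_rate`, guaranteeing every row and column
keeps at least one observation.  Survival times are exponential with
per-sample hazard `baseline · Π hazard_ratio(sets active in the sample)`
and uniform censoring on `(0, censoring_time_max]`; the defaults
(0.12/year, 10 years) give an expected event probability of
`1 − (1/1.2)(1 − e^{−1.2}) ≈ 0.42`.  ER status is Bernoulli (default 75%
positive, the typical cohort composition) or entirely unknown.

What the generator does *not* emulate: probe-affinity and batch effects,
heavy-tailed microarray noise, correlated background structure, and
non-proportional hazards.  Passing the planted-recovery and power tests
therefore demonstrates correctness of the machinery under the additive
block model, not detection performance on real arrays.

## Problem sizes and numerical choices

The standard benchmark is 200 probes × 60 samples with 10-probe sets
active in 15 samples; simulation-based checks use up to 2000 replicates
at n = 200.  Full grids at these sizes run in seconds; the overlap matrix
switches to a sparse representation beyond 4000 probes.  Hypergeometric
tails come from `scipy.stats.hypergeom.sf` (log-space stable).  Recovery
scoring matches each planted set to the family with the highest core
overlap, breaking ties by higher Jaccard similarity and then family
order, so a small exact family is preferred over a merged superset with
equal overlap.  All randomness flows through `numpy.random.default_rng`
seeds carried in configs.

## Known limitations

- Families are linked on gene membership only; a set whose membership
  drifts heavily across *s* can fragment into several families.
- The sentinel rule requires a curated sentinel/foil list; without one
  the `⌊s/2⌋` cap can admit near-saturated cells at large *s* (they
  consolidate into one giant low-Jaccard family and are easy to
  recognise, but they cost time).
- Overlapping biclusters are out of scope by construction: components
  partition the genes at each cell.
- The survival module reports unadjusted log-rank statistics; no
  multivariable modelling is attempted.
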