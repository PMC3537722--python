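# Methods

## The model

`ktheta` operationalizes the evolutionary genetic species concept: species
are inclusive populations evolving independently, whether because of
reproductive isolation or physical/ecological separation.  Under neutral
coalescent theory, a uniparental (mitochondrial or chloroplast) locus
sampled from one such population has nucleotide diversity

    pi  ~  theta = 2 * Ne * mu        (per site)

where `Ne` is the effective population size of the organelle genome and
`mu` the per-site, per-generation mutation rate.  After a clean split, the
mean pairwise difference between the two daughter populations grows as

    E[K] = theta * (tau + 1),   tau = T / Ne  (time in pairwise-coalescent units)

because a cross pair coalesces `T` generations of separation plus one
expected within-population coalescence time before the split.  Roughly 95%
of uniparental gene genealogies are reciprocally monophyletic by
`T = 4 * Ne` generations, at which point `K ≈ 8 * Ne * mu`, i.e.

    K / theta >= 4

is evidence that two clades are independently evolving populations rather
than transient clusters produced by drift.  Both `Ne` and `mu` cancel in
the ratio, which is why the method needs no external calibration.

## The procedure

1. Build a neighbor-joining tree from pairwise distances and bootstrap it
   (column resampling; default 1000 replicates).  Internal edges with
   support below 70% are collapsed.
2. Test sister clades from the tips toward the root.  For each clade,
   `d̄` = mean pairwise uncorrected difference, `pi = d̄·n/(n−1)`,
   `theta = pi/(1 − 4·pi/3)`.  When a clade's sequences are identical,
   `pi` is floored at `2/(L·n·(n−1))` (one pairwise difference of `1/L`).
3. Between the clades, `D` = mean uncorrected cross-pair difference and
   `K` = the model-corrected mean (JC69, K2P, or K81).  `D` feeds the ratio
   while `D < 0.05` (multiple hits negligible at that divergence); `K`
   otherwise.  Within-clade `pi`/`theta` always use uncorrected distances.
4. The ratio uses the **larger** of the two clade thetas (conservative:
   it can only shrink the ratio).  A singleton clade takes its theta from
   the sister clade.
5. Ratio ≥ 4 (inclusive) ⇒ the pair is frozen as two species; otherwise the
   pair is pooled into one putative species and `n`, `d̄` are recomputed on
   the union for every later test.
6. Each tested pair is annotated with a Monte-Carlo probability of
   reciprocal monophyly for the observed sample sizes, computed from the
   built-in two-population coalescent at `tau` mapped from the ratio
   (`tau = ratio` by default, `tau = ratio − 1` with the
   `ancestral_adjusted` mapping, which subtracts the expected ancestral
   polymorphism `E[K] = theta·(tau+1)`).

### Split qualification

The bare ratio rule needs small-sample safeguards; all are configurable and
every demotion is recorded in the pair-test log:

* Two sister singletons are *indeterminate* — theta cannot be estimated for
  either side — and are merged for upstream testing.
* A split whose deciding theta rests on the `d̄ = 0` floor is demoted to
  indeterminate.  The floor is an ad-hoc resolution limit, not an estimate,
  and splits based on it are not trustworthy.
* A singleton is only frozen as a species when its sister clade has at
  least 5 members (`min_sister_for_singleton`).  With fewer members the
  clade's theta is too uncertain at ratios near the threshold; users
  confident in a very large ratio can lower the gate.
* At least one side of a frozen pair must be a bootstrap-demonstrated
  clade: a cluster whose bipartition reaches the support threshold, or
  whose complement holds fewer than two leaves (an unfalsifiable split).
  Unions improvised while folding a collapsed polytomy match no supported
  bipartition and are not by themselves evidence of population structure;
  without this rule the tau = 0 negative control fragments badly.

### Polytomies and ladders

Collapsing weak edges creates multifurcations.  Children of a
multifurcation are folded together nearest-first by mean between-clade
uncorrected distance: the closest pair is tested first, and each further
child is tested against the nearest existing cluster — the pooled union
when earlier tests merged, or the nearer frozen clade when they split.
This resolves the testing-order rule for non-bifurcating trees, whose
published statement leaves the reference point ambiguous.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `model` | `uncorrected` | distance model (`jc69`, `k2p`, `k81` available) |
| `bootstrap_replicates` | 1000 | column-resampling replicates |
| `support_threshold` | 70 (%) | collapse edges below this support |
| `ratio_threshold` | 4 | the K/theta species cutoff (inclusive) |
| `d_switch` | 0.05 | use D below, K above this divergence |
| `prm_reps` | 1e4 (pipeline), 1e5 (`prm_estimate`) | Monte-Carlo replicates for P(RM) |
| `tau_mode` | `birky` | ratio→tau mapping for P(RM) |
| `min_sister_for_singleton` | 5 | singleton split gate |
| `seed` | required | drives bootstrap and P(RM) streams |

## The coalescent simulator

Time is measured in pairwise-coalescent units (1 unit = `Ne` generations
for a uniparental genome), so a within-population pair coalesces after an
expected 1 unit and the 4x calibration makes `tau = K/theta` exactly.  The
genealogy simulator draws within-population coalescences at rate 1 per pair
until `tau`, then lets the surviving lineages coalesce freely in the
ancestral population; it is cross-checked in the tests against `msprime`'s
split-demography model and against closed forms (P(RM) = 1/9 for 2+2
samples at `tau = 0`; `1 − (2/3)e^{−tau}` for 1+2 samples).

The alignment generator drops Poisson mutations on branches at rate
`theta_site/2` per site per unit, so the expected within-species pairwise
difference equals `theta_site` and the expected between-species difference
is `theta_site·(tau+1)` — both verified by the calibration tests
(200 replicates at `theta = 0.01`, `tau = 8`, `n1 = n2 = 10`, `L = 1000`).
Infinite-sites placement is the default (every mutation hits a fresh site;
an overflow raises with advice to enlarge `L` or switch to `jc` mode);
Jukes-Cantor mode permits multiple hits for saturation testing.

What the generator does *not* emulate: rate variation across sites or
lineages, selection, recombination, migration after the split, sequencing
error, and base-composition bias.  Passing the synthetic-recovery tests
therefore says the machinery is internally consistent with the neutral
clean-split model, not that real barcode data meet those assumptions.

## Numerical choices

* Pairwise deletion for gaps and ambiguity codes: a site is dropped only
  for pairs in which either sequence lacks an unambiguous A/C/G/T there.
  The trimming step keeps lone internal `N`s; only leading/trailing missing
  data are cut.
* Saturated pairs (a correction logarithm hitting its boundary) raise an
  error by default; callers can opt into flagging instead, and flagged
  pairs are excluded from K only, never silently from D.
* NJ ties on the Q criterion break toward the lexicographically smallest
  label pair; negative branch-length estimates are clamped to zero with the
  deficit moved to the sister branch.  Both make results platform-stable.
* Bootstrap supports are mapped onto the point-estimate NJ tree, not a
  consensus tree.
* Reports round `pi`/`theta` to 4 decimals and ratios to 1; full precision
  is kept on the underlying records.
* All randomness flows from a single seed through `numpy` `SeedSequence`
  spawning, making whole report bundles byte-identical across runs.

## Problem sizes used in the test suite

Stochastic checks run at sizes chosen to give stable Monte-Carlo verdicts:
closed-form P(RM) comparisons at 1e5 replicates (3-SE bands), generator
calibration at 200 simulated datasets, and the end-to-end recovery
experiment at 40 datasets per condition with 100 bootstrap replicates each.

## Limitations

The recursive, automated application of the ratio test over-splits
single-locus data.  Within one species, bootstrap-supported shallow
subclades are common whenever `theta·L` is large enough to resolve drift
structure (e.g. ~10 expected differences per within-species pair); support
selects clades with long subtending branches and shallow interiors, so the
subclade's own theta-hat underestimates the species' theta while its
distance to the sister clade overestimates the drift expectation, and
`D/theta-hat ≥ 4` occurs in roughly a quarter of panmictic samples of 20
sequences at `theta = 0.01`, `L = 1000`.  The measured consequence in the
recovery experiment: a deep split (`tau = 10`) is called exactly two
species in only ~45–60% of replicates (extra within-species splits
otherwise), and a shallow split (`tau = 0.2`) is called one species in
~70%.  This mirrors the method's published behaviour — it splits
recognized morphological species and its authors themselves discount some
of its own floored-theta splits — and is inherent to using a clade's
internal diversity as the yardstick for its own distinctness.  Users
should treat multi-species partitions of dense intraspecific samples with
caution and corroborate splits with independent evidence; the pair-test
table reports every demotion and every ratio so such judgements are
auditable.

A second caveat: the probability of reciprocal monophyly attached to each
pair is the *sample-level* P(RM) under the clean-split coalescent at
`tau` inferred from the observed ratio.  It is a descriptive annotation,
not the decision statistic, and it is close to 1 precisely when the ratio
is large — including for spurious splits.
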