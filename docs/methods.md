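# Methods

`gestnet` analyses dyadic social behaviour in a small fission–fusion
community observed by focal-animal sampling: who spends time within 10 m of
whom, and how directed gestural communication of different modalities
(visual, tactile, auditory short-range, auditory long-range) relates to
those proximity bonds.  This note documents the estimators, the permutation
tests, the synthetic-data model, and the numerical and design choices.

## Behavioural estimators

All duration measures use the instantaneous-scan estimator.  A focal follow
is 18 minutes: 9 scans at 2-minute intervals, each scan recording the
focal's party (individuals within a ~35 m spread), the subset within 10 m,
the nearest neighbour, the activity, and visual-attention flags.  Each scan
stands for 2 minutes of time, so for focal A and partner B

* **proximity bond strength** (min/hr) =
  `60 · #(A-focal scans, B within 10 m) / #(A-focal scans, B in party)`;
* **behaviour durations** (rest, feed, travel, grooming, visual attention)
  use the same denominator with an additional numerator condition; grooming
  additionally requires B to be the recorded grooming partner, and
  attention measures require B to be the nearest neighbour;
* **gesture rates** (events/hr) = `#(events A→B) / hours B was within 10 m
  of focal A`, with optional modality and context filters.  Only events
  whose recipient was within 10 m are analysis-eligible.

All matrices are directed (row = focal/signaller), label-addressed, and
carry an undefined (NaN) diagonal that no statistic touches.  Dyads whose
denominator is zero are recorded as 0 and listed in the matrix's `flagged`
set: the permutation tests need complete matrices, and deleting dyads would
change the permutation group.  Proximity rates are bounded by [0, 60] min/hr
because within-10 m scans are a subset of co-party scans.

**Bond classes.**  Thresholds are the mean ± ½·SD of all off-diagonal
directed proximity values (zeros included; population SD, since the cells
are the complete enumeration of dyads).  *Strong*: value ≥ upper (directed).
*Preferred reciprocated*: both directions ≥ upper (symmetric by
construction).  *Preferred non-reciprocated*: this direction ≥ upper, the
reverse below.  *Non-preferred*: value ≤ lower.  The three latter classes
are pairwise disjoint on directed cells and strong is the union of the two
preferred classes.  A constant matrix has no usable thresholds and raises.

**Degree centrality.**  Normalised degree is the mean of a node's row
(out-degree) or column (in-degree) over the n−1 off-diagonal cells; for
binary networks this is the proportion of possible ties.

**Similarity controls.**  Same-sex, same-matriline (maternal kinship) and
same-reproductive-state are 0/1 indicators; age proximity is −|ageᵢ−ageⱼ|
standardized over off-diagonal cells.  The kinship criterion is maternal
because matriline is the field-observable pedigree unit.

## Permutation inference

Dyadic cells are not independent — every cell involving individual A shares
A's idiosyncrasies — so all tests build their null distributions from
**node-label permutations**: rows and columns permuted simultaneously,
which preserves the dyadic dependence structure exactly.

**MRQAP with double semi-partialling.**  Matrices are vectorized
(row-major, diagonal skipped), z-scored with the population SD, and fit by
least squares (no intercept after centering); the reported coefficients are
therefore standardized.  For each predictor Xₖ: the residual eₖ of Xₖ on
the remaining predictors is reshaped into its n×n cells, node-permuted,
substituted for Xₖ with the other predictors fixed, and the refit
coefficient recorded.  Semi-partialling makes the per-predictor test robust
to collinearity among predictors and to skew.  Implementation detail: with
the other predictors fixed, the permuted-refit coefficient is computed in
closed form via partitioned regression,
`β*ₖ = e*ᵀM₋ₖy / e*ᵀM₋ₖe*`, with `M₋ₖ` the projector orthogonal to the
other predictors — algebraically identical to the full refit and fast
enough to vectorize over thousands of permutations.  Unit tests verify the
observed coefficients against an independent normal-equation solution and
against statsmodels.

Defaults: 2,000 sampled permutations for dyadic models, drawn uniformly
with replacement (identity allowed); the permuted statistic is the
standardized coefficient (a t-ratio option exists).  Two-tailed p-values
use the `(hits + 1)/(n_perm + 1)` convention — the observed arrangement
counts as one permutation, so p ∈ [1/(n_perm+1), 1] and is never 0 — and
ties with the observed statistic count toward the tail (conservative).
`mrqap_exhaustive` enumerates the full permutation group for n ≤ 7 as an
exact oracle; there p is the fraction of the n! permutations (identity
included) at least as extreme, so p ≥ 1/n!.

**Node-level regression.**  Standardized OLS of a per-individual outcome on
per-individual covariates; the null permutes the outcome vector across
individuals (10,000 permutations by default).  Permuting the raw outcome
(rather than residuals) is the simplest exchangeable scheme and is exact
under the global null.  Saturated designs are permitted deliberately: the
replica's centrality model has 12 predictors for 12 individuals, giving an
exact fit (r² = 1) via the minimum-norm solution, and inference rests
entirely on the permutation distribution of each coefficient.

**Geary's C.**  For attribute x and weights w,
`C = (N−1) Σ_{i≠j} w_ij (x_i−x_j)² / (2 W Σ_i (x_i−x̄)²)`.
Its permutation-null expectation is exactly 1; values below 1 mean tied
individuals have similar attribute values.  The two-sided p doubles the
smaller tail of the permutation null.  Weights may be the raw cell values
or their dichotomization; the function defaults to binary, but the
pipeline's sampling-effort check uses weighted mode because the benchmark
rate networks are dense (a ~99%-density binary network leaves C nearly
constant under permutation — correct level, no power).

**Multiple testing.**  Raw permutation p-values are reported without
correction across models, matching standard practice for these analyses;
any correction is left to the caller.

## The synthetic community

The generator exists to make the whole pipeline testable end to end with
known ground truth.  It emulates: 12 adults (six of each sex; configurable),
matrilines sized so ~10% of dyads are maternal kin, a third of females in
oestrus (static per dataset), per-focal sampling effort drawn uniformly
from 8.33–18.63 hours (follows of 18 min), fission–fusion party membership,
within-10 m proximity driven by a latent bond structure, and directed
gesture events with modality-specific context and distance distributions.

The latent model has two layers:

1. **Shared affinity axis.**  `affinity_ij = exp(noise_ij + 0.5·kin +
   0.3·same_sex)` with symmetric Gaussian log-noise (SD 0.8).  Affinity is
   multiplicative, so planted linear effects act on the standardized
   *log*-affinity z (z-scoring the raw log-normal values would hand the
   "linear" effects to a few extreme dyads).
2. **Modality channels.**  Each dyad carries an independent per-modality
   propensity `u_m` (log-rate SD τ = 0.55, mean-corrected so intercept
   calibration is exact).  The realized proximity latent is
   `standardize(z + κ·Σ_m γ_m·u_m)` with coupling κ = 10: dyads
   idiosyncratically fond of a modality shift their proximity in the
   direction of that modality's planted slope.  This is what makes the
   *partial*, per-modality bond association — the quantity the MRQAP is
   designed to isolate — a real feature of the data rather than an echo of
   one shared axis.  With a single latent, whichever modality is measured
   best absorbs it and all other partial coefficients are conditionally
   null; no intercept/slope setting escapes that, which we verified
   empirically before adopting the channel layer.

Party membership is Bernoulli per scan with
`logistic(logit(0.7) + 0.5·z_bond)`; within-10 m given co-party is
`logistic(−0.45 + 0.65·z_bond)` — the intercept keeps the community mean
near 23 min/hr of close proximity per co-party hour, in the range reported
for wild chimpanzee communities.  The nearest neighbour is the
highest-affinity individual within 10 m (ties by id order).  Gesture counts
per (scan × within-10 m partner × modality) are Poisson with mean
`(2/60)·exp(α_m + γ_m·z + τ·u_m − τ²/2)`; a gamma-Poisson overdispersion
option exists but defaults off.  Contexts follow modality-specific tables
(tactile mass on play/greeting/reassurance/grooming; auditory long-range on
threat/travel/copulation/pant-hoot; visual spread broadly), and
signaller–recipient distances are modality-specific truncated normals.

**Planted defaults.**  γ = +0.18 (visual), −0.18 (tactile), −0.06
(auditory short-range), −0.18 (auditory long-range); α = log 12 events/hr
for the three coupled modalities and log 0.4 for auditory short-range.
Two deliberate departures from field realism, made once at design time:

* *Rates are high.*  Real per-dyad gesture rates (order 0.3–1.6 events/hr)
  give only a handful of events per dyad in ~12 hours of focal sampling;
  dyadic rate matrices estimated from that are too noisy for
  resampling-stable recovery of partial coefficients.  The benchmark runs
  at ~12 events/hr so that rates are measured with little noise.
* *Slopes are small.*  The slopes act on the log-rate of a high-rate
  process; larger slopes produce rate matrices so skewed that linear
  network regression loses the planted signal to single extreme dyads.

Consequently, passing tests demonstrate that the estimators and tests
recover planted structure under well-conditioned sampling; they do not show
that 12 hours of real field data would suffice at field rates.

One master seed reproduces everything: `SeedSequence(seed).spawn(4)` yields
the population, affinity, scan and event streams, and the pipeline derives
a per-analysis sub-seed as `SeedSequence([master, key])` with fixed keys
(simulate 0, bond/modality 1, context/modality 2, centrality 3, sampling
effort 4).  Reports are byte-identical under a fixed master seed.

## Validation design

* **Exact oracles.**  OLS against hand normal equations and statsmodels;
  QAP permutation against a 3×3 index chase; sampled MRQAP p-values against
  exhaustive enumeration at n = 5 (3 binomial SE); the Geary permutation
  mean against the exact value 1 (exhaustive for n = 5 in-test, Monte Carlo
  at n = 12).
* **Calibration.**  With all planted slopes zero, MRQAP, node regression
  and weighted Geary each reject at 5% within [0.03, 0.07] over 200
  replicate communities (12 individuals, 15 follows each — the replicate
  size keeps the full calibration study inside a test-suite run).
* **Recovery.**  At the default planted effects with 40 follows per focal,
  the bond/modality analysis recovers all three tested slope signs with
  p < 0.05 in ≥ 18 of 20 replicates.  A sign counts as recovered when it
  appears in the planted direction in the preferred-reciprocated model or
  mirrored in the non-preferred model — the same two-sided pattern a
  bond-strength effect produces in practice (strong-bond ties enriched,
  weak-bond ties depleted, for a positively coupled modality).
* **Structure.**  Bond-class disjointness and symmetry, rate bounds,
  dichotomize/symmetrize idempotence, and exact invariance of observed
  statistics under simultaneous relabeling, all on fuzzed inputs.

## Numerical choices and edge cases

* z-scoring everywhere uses the population SD (ddof 0).
* Constant columns (outcome or predictor) raise `DegenerateInputError`
  naming the column; the pipeline drops constant *predictor* networks with
  a warning (sparse contexts are expected at synthetic scale) but lets a
  constant outcome raise.
* Rank-deficient dyadic designs raise (collinearity among predictors is an
  input error there); rank-deficient node-level designs fall back to the
  minimum-norm solution as described above.
* Tie comparisons use a relative tolerance of 1e-12 so the identity
  permutation always counts as extreme.
* Zero-denominator dyads: value 0 plus a flag, surfaced in the report
  provenance as per-matrix counts.
* A grooming activity drawn when nobody is within 10 m is recorded as
  `other` (grooming requires a partner).

## Limitations

* Gesture sequences are not modelled: every event is a single gesture.
  (Field protocols record gestures "singly or in sequences"; whether
  published rates count sequences or components is ambiguous, so the
  generator sidesteps the distinction.)
* No individual-level gregariousness parameter: node-level centrality
  effects are not planted, so the centrality analysis is validated for
  calibration and mechanics, not for node-level sign recovery.
* Oestrus is static within a dataset; no cycling.
* The channel-coupling layer is a benchmark device: it encodes the
  assumption that modality-specific communication styles feed back into
  proximity maintenance.  Real causal structure is surely richer.
* Party membership is independent across scans given the latent (no
  temporal autocorrelation within follows).
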