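# Methods

## Model and procedure

`rotsf` fits an ensemble of L survival CART trees to right-censored data
D = {(τ_q, δ_q, x_q)}, q = 1..n, with τ_q = min(U_q, C_q) the observed
follow-up time and δ_q = I(U_q ≤ C_q) the event indicator.  The ensemble's
distinctive step is the per-member *rotation* of the covariate space:

1. **Outer bootstrap.**  Member i draws D′, n subjects with replacement
   from D.  Subjects with zero draws form the member's out-of-bag (OOB)
   set — on average a fraction (1 − 1/n)ⁿ ≈ e⁻¹ of the sample.
2. **Variable partition.**  A uniformly random permutation of the p
   covariates is chopped into k = ⌊p/M⌋ subsets of size M; the trailing
   p mod M indices form the remainder set RV.
3. **Block PCA under double bagging.**  For each subset, an *inner*
   bootstrap D″ of size n is drawn from D′ and the subset's columns of D″
   are centered (no variance scaling, matching the original
   rotation-forest convention; scaling is exposed as an option) and
   decomposed by SVD.  All M principal-axis loading vectors are retained,
   ordered by decreasing explained variance — so no information within a
   subset is discarded.  The inner bootstrap exists *only* to perturb the
   loadings; it injects extra diversity between members beyond what the
   outer bootstrap provides.  With `double_bagging=False` (the "single
   bagging" variant) the loadings are computed on D′ itself; outer bags
   and partitions are drawn identically under the same seed, so the two
   variants differ exactly in the inner resample.
4. **Rotation assembly.**  The block loadings are placed on the block
   diagonal of a p × kM matrix, each row rearranged to its original
   variable position; RV rows are identically zero, so those covariates
   are invisible to this member.  When p mod M = 0 the matrix is
   orthogonal and the rotation is an isometry of the covariate space.
5. **Tree growth.**  A survival CART tree is grown on the rotated outer
   sample (τ_{D′}, δ_{D′}, X_{D′} Rᵃ) — the tree trains on D′, not on any
   D″, since a different D″ is drawn per subset and no single inner sample
   could serve as the training set.

### Base learner

Splits are selected by exhaustively scanning every rotated feature and
every midpoint of consecutive distinct values, maximising the absolute
standardized two-group log-rank statistic

    Z = Σ_u [d₁(u) − d(u) Y₁(u)/Y(u)] / sqrt(Σ_u v(u)),
    v(u) = d(u) (Y₁/Y) (1 − Y₁/Y) (Y − d)/(Y − 1),

summed over distinct event times u, with d(u) events and Y(u) subjects at
risk (censored subjects tied with an event time remain at risk at that
time).  Log-rank splitting is the dominant survival-CART criterion and is
among the standard criteria of random survival forests; the splitting rule
is a configuration point of the tree module.  A candidate with zero
variance carries no information and is encoded as NaN, never preferred
over any finite statistic.  Recursion stops when a node has fewer than
2·`min_node_size` subjects, no events, or no admissible split; there is no
depth limit and no pruning — ensemble members are deliberately low-bias,
consistent with forest practice.  Each leaf stores the Nelson–Aalen
cumulative hazard Ĥ(t) = Σ_{u≤t} d(u)/Y(u) of its subjects on the tree's
grid of unique training event times.

### Prediction and risk score

A new subject is rotated with each member's Rᵃ, routed to a leaf
(`x[v] ≤ threshold` goes left, ties inclusive), and the member CHFs are
carried onto the pooled training event-time grid by right-continuous step
interpolation (zero before the member's first event time, last value
carried forward).  The ensemble CHF is the unweighted mean over members —
averaging Nelson–Aalen member estimates follows the random-survival-forest
design this ensemble builds on.  The scalar risk score is the sum of the
ensemble CHF over the grid, a mortality-style score: it is strictly
monotone in pointwise CHF ordering, which is all the concordance index
consumes.

### Variable importance

The mean C-index decrease of covariate v is

    VI_v = (100 / L) Σ_j (C_j − C̄_j),

where C_j is Harrell's concordance of member j's risk predictions on its
own OOB subjects and C̄_j the same after permuting v's values *among those
OOB subjects only*, one permutation per member (a replicate knob exists
for variance reduction; it defaults to 1 and averages within member).
The permutation happens in the original covariate space before rotation —
the only reading under which "permuting covariate v" names an actual
covariate — so a member whose remainder set contains v contributes exactly
zero.  Members whose OOB set admits no permissible concordance pair are
skipped and the divisor reduced accordingly.  Importance is reported per
*original* covariate, never per rotated feature.  Negative values occur
for noise covariates (permuting a covariate the trees overfit in-bag can
slightly improve OOB concordance); their magnitude shrinks with n and L.

### Evaluation statistics

Harrell's C-index counts ordered pairs (i, j) as permissible when the
shorter observed time belongs to an event: t_i < t_j with δ_i = 1, or
t_i = t_j with δ_i = 1, δ_j = 0.  Tied-time pairs with two events are
excluded; a permissible pair scores 1 if the shorter-surviving subject has
the strictly higher risk, 1/2 on a risk tie.  These sub-rules match the
convention of the widely used survival libraries and are frozen by
exhaustive pair-enumeration oracle tests.

Model comparison over n repeated runs of m models ranks each run's scores
(higher score → higher rank, average ranks on ties) and computes

    FT = 12/(n m (m+1)) Σ_j (Σ_i r_i^j)² − 3 n (m+1),

referred to a χ²(m−1) null, with the Nemenyi post-hoc statistic
z = (R_{j1} − R_{j2}) / sqrt(m(m+1)/(6n)) for pairwise contrasts and a
paired Wilcoxon signed-rank test (scipy) for two-model comparisons.  No
Nemenyi critical value is hard-coded: published tables disagree at the
fourth decimal, so comparisons accept a user-supplied cutoff and a helper
returns the studentized-range reference q_α(m, ∞)/√2.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L` | 1000 | ensemble size; test profiles use 30–100 |
| `M` | 2 | covariates per rotation subset (k = ⌊p/M⌋ blocks) |
| `min_node_size` | 6 | minimum subjects per leaf; no depth limit |
| `double_bagging` | on | inner bootstrap for the PCA loadings (off = RotSFsb) |
| `scale` | off | variance-scale blocks before PCA |
| `seed` | 0 | master seed; member i's substream is spawned independently of L |

Seeding contract: one master `SeedSequence` spawns a per-member child, so
member i's bootstrap, partition and inner resamples are invariant to the
ensemble size and to execution order; fitting twice with one seed is
bit-reproducible.

## Synthetic data

The generator draws covariates as standard normals (optional
equicorrelation ρ via a shared factor, or a symmetric binary model for
depth-one tree tests) and event times from a proportional-hazards model
with exponential baseline: U ~ Exp(λ₀ e^{xβ}), λ₀ = 1 by default.  A
Weibull baseline (shape parameter) is exposed as an option.  Censoring
times are independent exponentials whose rate λ_c is calibrated to the
target expected censored fraction: in closed form λ_c = λ₀ q/(1−q) when
β = 0 with the exponential baseline, otherwise by bisection on
E[censored | drawn U] = mean(1 − exp(−λ_c U_q)), which is exact given the
drawn event times and monotone in λ_c, so a root exists for every target
below 1.  Default target 0.3 reflects typical clinical-cohort censoring;
the three benchmark shape templates (418/17 at 61.5%, 507/5 at 21.3%,
137/6 at 6.6%) reproduce the (n, p, censoring) triples of classic
PBC/CML/Veteran cohorts with moderate two-covariate effects
(β₁ = 0.5, β₂ = −0.5) so shape-faithful integration tests carry signal.

What the generator does *not* emulate: real clinical covariates are mixed
continuous/categorical, skewed, and correlated in structured ways;
censoring can be informative; hazards can be non-proportional.  Passing
tests therefore demonstrate correctness of the algorithms and recovery of
planted proportional-hazards structure, not performance on any real
cohort.

## Numerical choices and edge cases

* Log-rank zero-variance candidates → NaN sentinel, never selected; split
  ties broken toward the lowest variable index, then lowest threshold.
* PCA sign ambiguity fixed by making each loading column's
  largest-magnitude entry positive; rank-deficient blocks (constant
  columns, duplicated bootstrap rows) are completed to an orthonormal
  basis via SVD rather than failing.
* Datasets with zero events are rejected at construction; a node subset
  with zero events becomes a leaf with an identically-zero CHF.
* OOB risk is NaN (flagged, never imputed) for subjects in every bag —
  possible only for small L, since the no-coverage probability decays as
  (1 − e⁻¹)^L.
* The model serializes to a versioned JSON container (config, partitions,
  loadings, tree structures, grids) for refit-free prediction.

## Test-profile problem sizes

Unit and property tests run at n ≤ 150, L ≤ 50.  End-to-end calibration
checks use n = 300, L = 100 (null behavior, signal recovery) and a
50-repetition 80/20-split comparison of the double- and single-bagging
variants at n = 200, L = 50 — sizes chosen as desk-scale defaults that
keep the whole suite in a few minutes while leaving the binomial/bootstrap
tolerances meaningful.

## Known limitations

* Competing risks, time-varying covariates, case weights and
  survival-probability calibration are out of scope.
* The C-index is the only built-in accuracy metric (no time-dependent AUC
  or Brier scores).
* Permutation importance inherits the usual caveats under strongly
  correlated covariates (importance is shared or masked); one permutation
  per member keeps the estimate cheap but noisy at small n.
* The concordance computation is O(n²) in memory and time; fine for
  cohort-scale data, not for n in the hundreds of thousands.
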