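# Methods

`holeboard` implements a two-phase workflow for handling inter-individual
variability in mouse behavioral experiments: phase 1 characterizes each
animal's *individual response type* from repeated modified-Hole-Board (mHB)
trials; phase 2 exploits the types in the design and analysis of a
pharmacological experiment. This note records the models, the defaults and
why they were chosen, and what the synthetic data generator does and does
not emulate.

## Integrated behavioral z-scores

Each 5-minute mHB trial yields counts (e.g. board entries, rearings, hole
explorations, line crossings), latencies (capped at the 300 s trial
ceiling; an animal that never shows the event carries the ceiling), and the
percentage of time on the unprotected board. Variables measuring the same
underlying dimension — avoidance behavior, exploration, locomotion — are
z-scored against the *pooled* cohort (all strains together; per-strain
references would remove exactly the between-strain signal later stages
need), direction-aligned, and averaged into one integrated score per
dimension per mouse per trial.

Direction signs make a larger score mean more of the named dimension: board
entries and % time on board enter avoidance with sign −1 and the latency to
first board entry with +1; for exploration and locomotion, counts enter
with +1 and latencies with −1. The member lists and signs are
user-overridable (`DimensionSpec`). SDs use the n−1 denominator (sample
statistic on a finite cohort). A zero-spread variable raises an error
naming the variable rather than silently producing infinities.

## Residual trajectories

Habituation is a *trajectory* phenotype, so nuisance structure is removed
with a linear mixed model that deliberately excludes trial: per dimension,

    score ~ strain + experimenter            (fixed)
            + (1 | mouse) + (1 | test group) + (1 | test order)   (random)

with continuous-time AR(1) correlation across a mouse's trials
(corr = φ^Δt) and a separate residual-SD multiplier per strain
(heteroscedasticity weights). Before fitting, avoidance is
log-transformed, exploration square-root-transformed and locomotion
rank-transformed (average ranks). Because integrated z-scores can be ≤ 0
and no canonical shift exists, the transforms use x − min(x) + 1 (log) and
x − min(x) (sqrt): minimal, deterministic, order-preserving.

Estimation is REML on the marginal covariance
V = σ²[Σ γ_k Z_k Z_k' + W^{1/2} C(φ) W^{1/2}], with variance ratios γ_k, φ
and weights profiled numerically (Powell) and σ² profiled in closed form.
Likelihood evaluations exploit the block-diagonal error part plus the
Woodbury identity for the random effects, so a full-cohort fit
(895 observations) takes ~1 s per dimension. The engine was cross-checked
against `nlme::lme` with the identical model on a small cohort
(standardized residuals agree to r > 0.999, max |Δ| < 0.05); no installed
Python package fits this covariance family (statsmodels' MixedLM has
neither residual correlation structures nor variance functions), which is
why the engine is in-house. If the full covariance fails to converge the
fit falls back to φ = 0 with weights retained, then to the
fixed-effects-only fit, logging each step.

Residuals are *conditional* standardized Pearson residuals: observed minus
fixed-plus-predicted-random effects, divided by the model-implied residual
SD of the observation's stratum (σ · w_strain). Whether the original
procedure standardized marginally or conditionally is not determinable;
the conditional choice subtracts the mouse intercept, which is desirable
here because the *shape* of the trajectory, not its level offset from
nuisance grouping, carries the phenotype. The choice is flagged in the
output metadata.

F-tests elsewhere in the package use the between/within denominator-df
convention (observation-level terms: N − g − p_within; group-level terms:
g − p_between − 1), the convention `nlme` uses. At phase 2 this gives
(1, 69) where 68 is sometimes quoted for this layout; the one-df difference
is bookkeeping, not substance, and no decision here depends on it.

## Longitudinal clustering

A mouse's datum is its joint 5-trial × 3-dimension residual trajectory;
distance is the Frobenius norm of the difference (plain Euclidean over the
15 entries — the residualization stage already standardizes each dimension,
so no further rescaling is applied). Clustering is best-of-restarts Lloyd
k-means: each restart initializes from k distinct trajectories sampled
without replacement from a stream seeded by (seed, k, restart), so results
are reproducible and adding restarts can only improve (never change
earlier streams). After Lloyd converges, a Hartigan-style single-point
exchange pass refines the partition with exact size-corrected SS deltas;
this escapes batch-update fixed points and makes tiny instances (n ≤ 10)
provably reach the enumeration optimum in the test oracles. Empty clusters
are repaired by reseeding from the point farthest from its center;
iteration cap 100.

Whether the data support any partition at all is decided first by the gap
statistic (uniform-box reference over each feature's observed range,
B ≥ 10 reference sets, one-standard-error rule at k = 1). The number of
clusters is then a majority vote of three cluster-validity indices —
Calinski–Harabasz (maximize), Davies–Bouldin (minimize), Ray–Turi
(minimize) — over k = 2..6, ties toward the smallest k. The plain majority
vote is a documented stand-in for the published CVI-voting variants, and
the index set is config-overridable.

Recovered clusters are characterized per dimension with
score ~ cluster × trial (both categorical, sum-coded) plus a random
intercept and a random (centered-)trial slope per mouse, independent
components; contrasts (cluster difference at each trial; trial 5 − trial 1
within cluster) report estimate, SE, t, p and Cohen's d = estimate / σ.

## Bootstrap stability

B = 200 samples of n mice drawn with replacement are re-clustered at the
base k (50 restarts per sample for tractability; overridable), aligned to
the base solution by maximum-overlap assignment (Hungarian algorithm on
the shared-individual contingency table), and each mouse scores a hit when
it lands back in its base cluster. The per-mouse Jaccard index divides
hits by the number of samples *containing* the mouse: any given mouse is
absent from ≈ 36.8% of bootstrap samples, so dividing by the raw B would
bound the index near 0.63 and conflate resampling noise with instability.
The raw-B convention is reported alongside (`jaccard_raw_b`), as is the
total occurrence count with multiplicity (which sums to B·n across mice).
Per-cluster stability is the mean over the cluster's members.

## Phase-2 design

96 characterized mice form 48 treatment–control pairs, 16 per strain.
Pairs are matched on body weight within strain and within experimenter;
the *balanced* half is additionally matched on response type, the
*unbalanced* half mimics a conventional experiment that ignores it.
Weight matching pairs adjacent animals on the weight-sorted list — a
deterministic rule that attains the brute-force minimum total within-pair
difference (verified by enumeration in the tests). Balanced cells are
filled first (they are the constrained ones), then unbalanced cells from
the remaining animals, selections seeded. The layout is a complete
randomized block design: one pair per (block × experimenter × strain ×
pool) cell, 4 blocks = 4 test days; treatment (dexmedetomidine vs saline)
is a fair coin within each pair; balanced and unbalanced pairs alternate
in the within-block test order.

## Phase-2 analysis

Per dimension (exploration log-shifted, locomotion rank-transformed,
avoidance untransformed), the factorial model

    score ~ treatment * strain * pool * experimenter + (1 | block)

is fit as a linear mixed model (this is the concrete reading of a "GLM
with a random block"), with all interactions, sum-to-zero coding, Wald
F-tests at between/within df. Effect sizes are partial
η² = SS_eff/(SS_eff+SS_err) with 95% CIs by noncentral-F inversion
(no canonical CI method is mandated; noncentrality inversion is the
standard choice) and the neurobehavioral bands small ≤ 0.03 < medium
< 0.10 ≤ large < 0.20 ≤ very large. Post hoc estimated-marginal-mean
contrasts average cell predictions with equal weights, test against the
Dunn–Šidák-adjusted α = 1 − (1−α)^(1/m), and report Cohen's
d = estimate / model residual SD with bands at |d| = 0.5 / 1.0 / 1.5.

`compare_pools` classifies each term by where it reaches significance:
*both*, *neither*, *augmented* (unbalanced pool only — response-type
variation inflating an apparent effect) or *unmasked* (balanced pool only —
an effect visible once type variation is controlled).

## The synthetic cohort generator

The generator produces the study conditions every stage assumes: 59/60/60
mice of strains C (BALB/c-like), B6N and 129S2; five trials; two latent
response types mixed within every strain with per-strain type-A
probabilities 0.119 / 0.70 / 0.90 (matching the published strain-by-cluster
distribution); weekly test batches of 30 (10 per strain) giving test-group
and test-order factors; near-even experimenter split per strain; strain-
specific body weights (means 20.4/21.0/24.1 g).

Type mean trajectories are monotone linear ramps qualitatively matching
the published cluster shapes — type A: avoidance −0.5→+0.5, exploration
flat at −0.2, locomotion +0.2→−0.4; type B: avoidance +0.5→−0.5,
exploration −0.3→+0.6, locomotion −0.3→+0.6 (z units). The magnitudes are
free parameters: no numeric cluster-mean trajectories are available to
calibrate against, so the defaults are qualitative stand-ins chosen to
give clear but not trivial separation (≈ 2 within-type SDs per trial at
the default noise). Noise: per-mouse random intercept SD 0.25 per
dimension, CAR(1) trial-to-trial noise with SD 0.30 and φ = 0.4, both in z
units — values a repeated-measures behavioral assay of this kind
plausibly shows, fixed once. Nuisance effects default to modest additive
shifts (experimenter E1 +0.15 z avoidance / −0.15 z exploration; strain
offsets ≤ 0.4 z).

Raw ethogram variables are emitted as affine-plus-noise readouts of the
latent dimension score (counts rounded and floored at 0, latencies clipped
to [0, 300] s, the percentage to [0, 100]), so the scoring stage has
realistic multi-variable input; only dimension-level trajectories are
published, so the variable-level map is the package's own construction.

Phase 2 simulates one trial per enrolled mouse: strain + experimenter +
type offset (by default each type's trial-5 trajectory value — the
animal's post-habituation state) + treatment effect for treated mice
(defaults +0.3 z avoidance, −0.6 z exploration, −0.8 z locomotion:
activity suppression with mildly elevated avoidance, the qualitative
signature of a sedative α2-agonist) + a between-test-day block effect
(SD 0.2 z; day-to-day variation is the reason the block factor exists)
+ individual and residual noise.

What the generator does **not** emulate: floor/ceiling clumping of real
latencies (beyond hard clipping), count overdispersion, within-trial
time-budget constraints between behaviors, sex or estrous effects,
corticosterone, drift of experimenter effects over weeks, and any
dependence of type on body weight. Passing tests therefore demonstrate
that the pipeline recovers structure *of the kind assumed*, at realistic
sizes and noise — not that real mHB data satisfy these assumptions.

## Problem sizes in the test-suite simulations

Monte-Carlo suites use sizes chosen to make their sampling error small
relative to the margins being asserted: 1000 cohort replicates for the
type-mixture expectation; 50 full-size cohorts for label recovery;
1200 replicates for type-I calibration; 500 for the within-pair variance
comparison; 300 each for the two constructed confounding scenarios
(which use 50/50 type mixtures and ±0.75 z type offsets so the confound
they are built to demonstrate is actually present at detectable size).

## Known limitations

- CVI voting is a plain majority over three indices; published adjusted
  voting schemes differ in unreported details.
- Random effects are independent components (no intercept–slope
  covariance); the characterization model centers trial to keep this
  approximation mild.
- Wald F-tests with plug-in variance components and between/within df are
  slightly liberal in very small block counts; no Kenward–Roger or
  Satterthwaite correction is implemented.
- The partial-η² CI assumes the noncentral-F monotonicity in λ and clamps
  at 0/1; bands at exact cut points follow the stated inequalities.
- The builder does not attempt to reproduce any particular same-type /
  mixed-type split among unbalanced pairs; that split is an outcome of the
  cohort's type mixture, not a design target.
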