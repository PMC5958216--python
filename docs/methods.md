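# Methods

## The model

`dinadif` simulates and analyses dichotomous test data under the DINA model
(deterministic inputs, noisy AND-gate), the most parsimonious conjunctive
cognitive diagnostic model.  A test of J items measures K binary latent
attributes through a J×K binary Q-matrix; examinee i's attribute profile is
α_i ∈ {0,1}^K.  The ideal response to item j is the AND-gate

    η_ij = ∏_k α_ik^{q_jk},

and the observed response is a noisy Bernoulli draw

    P(X_ij = 1 | α_i) = (1 − s_j)^{η_ij} · g_j^{1 − η_ij},

with slipping s_j (failing despite full mastery) and guessing g_j
(succeeding without it).  Mastery may never hurt: g_j ≤ 1 − s_j.  The
generator draws s_j, g_j ~ U[0.1, 0.3], which keeps that constraint strict by
construction.

## The simulation design

The package reproduces a fully crossed two-group Monte-Carlo design
(357 cells):

* **DIF patterns (16 + baseline).**  The focal group's parameters on six
  designated DIF items are shifted by (Δg, Δs) = (g_F − g_R, s_F − s_R).
  Magnitudes are 0.075 ("moderate") or 0.10 ("large"); same-sign shifts are
  labelled *uniform* DIF, all other nonnull combinations *nonuniform* — the
  labelling convention of the DIF literature this design follows, expressed
  on the parameter scale.  Per size: 2 uniform + 6 nonuniform patterns.
* **Q-matrix misspecification (6 + none).**  10% of the Q entries
  (round-half-up: 16 of 155) are flipped 0↔1, positioned at random, only
  within low-complexity items (≤ 2 required attributes), or only within
  high-complexity items (≥ 3), and impacting either both groups or the focal
  group only.  Flip sets that would leave an item requiring no attribute are
  re-drawn.
* **Attribute correlation (3).**  Profiles come from a K-variate standard
  normal with equicorrelation ρ ∈ {0.3, 0.5, 0.8}, dichotomized at 0.

**Generation vs. analysis semantics.**  A group impacted by misspecification
has its *data generated* under the flipped Q, while every analysis
conditions on the original Q.  This realizes the design's motivating
scenario — different groups truly operating under different Q-matrices while
the analyst uses a single one — and produces the expected asymmetry: flips
applied identically to both groups leave the groups exchangeable (little
harm to score-based tests), flips in the focal group only induce structural
group differences.  Whether misspecification instead contaminates only the
analysis Q is a legitimate alternative reading; the generation-side reading
is the one implemented.

**Frozen fixtures.**  Three inputs are fixed study-wide so that per-item
rates are comparable across conditions:

* the 31×5 Q-matrix — all 31 nonempty subsets of five attributes, ordered by
  (row sum, lexicographic).  This gives items measuring one to five
  attributes, a single-attribute anchor per attribute (completeness), and
  15/16 items in the low/high complexity strata;
* the six DIF items (~20% of the test) — one stratified seeded draw, three
  per complexity stratum, frozen in `fixtures/study_dif_items.json`;
* the baseline parameter draw — one U[0.1,0.3] draw whose realized means
  (s̄ = 0.226, ḡ = 0.184) match the generating conditions the design
  prescribes, frozen in `fixtures/baseline_item_parameters.csv`.

The flip set for a misspecified condition is re-drawn per replication (it is
part of the replication's randomness), unlike the three fixtures above.

**Seeding.**  Replication r of condition c derives its seed from
(base seed, CRC-32(condition id), r), so any cell can be regenerated in
isolation and results are independent of execution order or parallelism.

## Estimation

The DINA model is fitted by marginal maximum likelihood over the 2^K latent
classes via EM.  E-step: class posteriors ∝ π_c ∏_j P(x_ij|η_jc), computed
through one N×C matrix product using
Σ_j [x log p + (1−x) log(1−p)] = x·(log p − log(1−p))ᵀ + Σ_j log(1−p).
M-step: closed-form updates of each (s_j, g_j) from expected correct counts
split by η, and of π from posterior mass.  Defaults: start at s = g = 0.2
with uniform π (inside the generating range, avoiding symmetry traps);
converge when no parameter moves more than 1e-4; at most 1000 iterations
(the engine caps its per-item fits at 400); M-step estimates clipped to
[0.001, 0.5], which enforces g < 1 − s and prevents boundary collapse and
label switching.  Non-convergence is flagged, never silently accepted.

The two-group variant shares all item parameters across groups except a
single studied item, whose (s, g) are group-specific, with group-specific
mixing proportions.  Inside the engine a fully shared two-group fit is
computed once per replication and warm-starts all 31 per-item fits — the
per-item optimum is a small perturbation of the shared one, so this cuts EM
iterations several-fold without changing the solutions.

**Covariance.**  Parameter covariance is the inverse of the
outer-product-of-gradients (OPG) information, the empirical cross-product of
per-examinee score vectors of the marginal log-likelihood at the estimates.
Score formulas use the posterior AND-gate probability h_ij = P(η_ij = 1|x_i):
∂ℓ_i/∂s_j = h_ij(−x_ij/(1−s_j) + (1−x_ij)/s_j), the g-score mirrors it on
1 − h, and mixing-proportion scores eliminate the last class.

## The three DIF tests

All tests flag at α = 0.05 with no multiple-testing adjustment (the study
reports raw per-item rejection rates).  The matching score for the
score-based tests is the number-correct total *including* the studied item,
and no purification loop is run — the defaults of the standard
implementations.

* **Mantel–Haenszel.**  Examinees stratified by total score (0..J); per
  stratum a 2×2 group × correct table; classical continuity-corrected MH
  chi-square, df = 1.  Strata with a zero margin have zero variance weight
  and drop out automatically; the continuity correction can be toggled.
* **Logistic regression.**  For the studied item, the 2-df likelihood-ratio
  test of M1: logit P = β₀ + β₁·score + β₂·group + β₃·group·score against
  M0 without the group terms, targeting uniform and nonuniform DIF jointly
  (conditions mix both, and one flag per item per method is reported).
  Responses are collapsed to binomial counts per (score, group) cell and
  fitted with statsmodels GLM; separation or non-convergence marks the
  item's result invalid for that replication rather than mis-flagging it.
* **Wald.**  From the two-group fit with the studied item freed,
  W = dᵀV⁻¹d with d = (g_F − g_R, s_F − s_R) and V the covariance of d,
  referred to χ²(2).  By default V comes from inverting only the studied
  item's own 4×4 OPG block — the item-wise incomplete-information
  convention of the standard CDM software implementations of this test.
  Ignoring cross-parameter information understates sampling variance, and
  that understatement is precisely what gives the classical Wald DIF test
  its inflated Type I error (clearly visible in this pipeline's own output:
  Wald Type I error runs well above 0.05 even with a correctly specified
  Q).  `studied_item_covariance(..., information="full")` switches to the
  full-parameter OPG pseudo-inverse, which is the corrected variant and is
  close to nominally calibrated; it is not the default because the study's
  subject is the test as practised.

## Outcomes

Per condition, per-item flag proportions across replications are rolled up
into Type I error (mean over the 25 non-DIF items) and power (mean over the
6 DIF items), overall and split by the complexity strata (≤2 vs ≥3
attributes, judged on the true Q).  Because these are plain means, averaging
over items then replications or the reverse is identical.  Replications with
failed fits contribute only their valid cells; conditions with >20% failures
are flagged via `DifResultTable.failure_rate`.

## Problem sizes and what the checks show

Full scale is 357 conditions × 100 replications with per-item EM fits for
the Wald test — a cluster-scale job.  The packaged reproduction
(`scripts/acceptance.py`) runs the large-uniform-DIF slice at desk scale:
30 replications per condition (50 for the correctly specified Q at ρ = 0.5),
N = 1000 per group throughout.  At these sizes the binomial Monte-Carlo
standard error of a single condition-level rate is about 0.01–0.03, which is
the width built into the stochastic test bands.  The synthetic generator
reproduces the designed data structure exactly (conjunctive responses,
equicorrelated mastery at 50% marginal prevalence, uniform parameter draws);
it does not emulate real-data features such as unequal group sizes,
non-exchangeable attribute structures, hierarchical attributes, or
model misfit beyond Q-entry flips, so passing tests certify behaviour under
the design's assumptions, not on operational data.

**Matching-score contamination.**  The score-based tests match on the total
score *including* the six DIF items (no purification loop), so under large
DIF the matching variable itself differs between groups and their Type I
error on truly invariant items runs somewhat above the nominal level — the
well-known cost of conditioning on an observed total score rather than the
latent profile.  The purification-free convention is deliberate (it is the
default of the classical implementations); how much contamination a given
study sees depends on the Q-matrix rows and identities of its DIF items, so
pipelines built on different frozen fixtures will sit at somewhat different
points above nominal.

## Known limitations

* Only the DINA model; no G-DINA/LCDM generality, no polytomous items, no
  higher-order or hierarchical attribute structure, no Bayesian estimation.
* Misspecification is injected, never estimated; no Q-matrix validation or
  refinement methods.
* The marginal mastery proportion behind the attribute generator is fixed at
  0.5 (threshold 0); the threshold is exposed as an argument but the design
  does not vary it.
* Wald calibration is sensitive to the information variant (see above); both
  variants are OPG-based, and an observed-information alternative is left as
  future work.
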