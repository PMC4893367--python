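# Methods

This note documents the models, algorithms, numerical conventions and
deliberate design choices behind `grmcalib`, and states what the synthetic
data can and cannot establish.

## Graded response model and estimation

The GRM for a 5-category item is parameterized by a slope `a > 0` and
strictly ordered thresholds `b1 < b2 < b3 < b4`; cumulative probabilities
are logistic in `a(θ − b_k)` and category probabilities are their adjacent
differences.

Item parameters are estimated by Bock–Aitkin MML-EM
(`GradedResponseModelMML`):

* **Quadrature.** 61 equally spaced nodes on [−6, 6]; weights are the
  standard-normal density renormalized to sum to 1. A group with latent mean
  μ reuses the *same* nodes with exponentially tilted weights
  (∝ w_q·exp(μθ_q), renormalized), which equals the discretized N(μ, 1)
  density. A single fixed node set lets every group contribute to one set of
  expected counts and keeps all updates coordinate-ascent steps on one
  quadrature-defined objective, so the marginal log-likelihood trace is
  provably non-decreasing (asserted at 1e−8 in the tests). Truncation error
  is negligible for all study settings (a mean of −2 leaves < 4e−5 prior
  mass outside the grid).
* **E-step.** Posterior node weights per person, multiplied by the person's
  case weight when accumulating expected category-by-node counts. Case
  weights enter only there and in the per-person log-likelihood terms — a
  pseudo-likelihood treatment of sampling weights.
* **M-step.** Per item, L-BFGS-B on z = (log a, b1, log gap₂, log gap₃,
  log gap₄) with analytic gradients. The transform enforces positivity and
  strict ordering without constrained solvers; bounds keep a ≤ 10
  (divergence guard, warned when hit) and gaps ≥ 0.01, which also covers
  items with an unobserved *interior* category (the likelihood drives the
  corresponding gap to its floor; a warning is logged, the 5-category
  structure is kept).
* **Group means.** In multi-group fits one mean is fixed (the study fixes
  the clinical mean at 0; all latent SDs are 1). Each free mean is updated
  by a bounded 1-D maximization of the marginal likelihood in that
  coordinate, between the E- and M-steps. Start value: difference of group
  mean sum-scores divided by the pooled sum-score SD.
* **Start values.** a = 1.5 for every item; thresholds at normal quantiles
  of the observed (weighted) cumulative category proportions, clipped to
  [−4, 4] and gap-separated.
* **Convergence.** Largest absolute change of any item parameter or free
  mean < 1e−4, max 500 EM cycles; non-convergence returns a fit flagged
  `converged=False` with a warning, never an exception.
* **Unidentified thresholds.** If an item's *top* category is never
  observed, the MLE of b4 is +∞ and any finite number is a reporting
  convention. Since the likelihood is flat in a threshold beyond the
  quadrature support, fitted thresholds are clamped to [−6, 6] at the end of
  `fit` (warned, ordering preserved). This bounds the damage a single empty
  cell can do to bank-level summaries but cannot remove the upward bias of
  near-empty top categories (see Limitations).

`marginal_loglik` is exposed separately and is the exact objective the EM
maximizes; the tests verify the fitted solution against a direct numerical
maximization of it on a small instance, and the reported `loglik_` equals an
independent evaluation at the fitted parameters.

## Latent-trait scoring

`map_score_matrix` maximizes the log posterior Σ log p(x_j|θ) − θ²/2 by
safeguarded Newton iterations (vectorized over persons, backtracking when a
step would decrease the posterior, golden-section fallback for stragglers,
search range [−8, 8], gradient tolerance 1e−6). The reported SE is the
curvature SE, (−d²logpost/dθ²)^(−1/2) at the mode, which includes the
prior's one unit of information; the source study does not define its SE, so
this conventional choice is a replication caveat. MAP is finite for every
pattern, including the all-lowest pattern that dominates quasi-trait data —
that is why the study uses it — at the price of shrinkage toward 0 wherever
the bank is uninformative (θ ≲ −1.5 for this bank profile). Bounded
maximum-likelihood scoring (no prior, default clamp [−4, 4]) is available
via `MAPScorer(method="ml")` but is not used in replication runs.

## Synthetic world

* **Item bank.** 40 five-category items. Only the per-parameter min/mean/max
  profile of the original bank is published, so `generate_bank` draws each
  parameter column from a Beta distribution rescaled to [min, max] with the
  target mean (concentration 4), rejection-resampling each column until its
  own min/mean/max are within ±0.15 of target, sorting thresholds within
  item and enforcing a minimum gap of 0.05. Thresholds sit mostly above 0
  ("quasi-trait"): a general-population sample answers mostly in the bottom
  category. Columns are drawn independently — the joint distribution
  (e.g. any a–b correlation) of the original bank is unknown; this is a
  stated generator default, not an estimate.
* **Scenario 1 (two distributions).** General θ ~ N(−2, 1), clinical
  θ ~ N(0, 1); exact group counts (e.g. 750 + 750 at 50%). Proper analysis:
  two-group GRM, clinical mean fixed at 0, general mean free.
* **Scenario 2 (one distribution).** θ ~ N(0, 1) split at the critical
  value c = Φ⁻¹(1 − prevalence) = 1.28 at 10% prevalence (assumed known);
  groups drawn from the two truncated regions by inverse-CDF. Proper
  analysis: case-weighted MML with weights (1−p)/(1−f) and p/f (1.8 and 0.2
  at 50%), which sum to the sample size and whose weighted empirical
  distribution converges to the untruncated normal (tested by weighted
  Kolmogorov–Smirnov distance at n = 10⁵).
* **Responses.** One uniform draw per person-item cell compared against the
  item's cumulative probabilities — a single RNG stream, reproducible.
  Complete data only; no missingness, response styles or DIF.
* **Recovery experiment.** n = 1500 per calibration sample; clinical
  fractions 25/50/75%; 12 calibrations. Person recovery simulates 500
  respondents at each of 17 true θ values (−4 to 4, step 0.5) *from the true
  bank*; the same dataset (one seed branch per replication) is scored under
  all 12 estimated banks so differences are attributable to calibration
  alone. Reported: per-parameter Pearson correlations and mean(true −
  estimate) (negative = overestimation), pooled θ correlation, pooled
  mean(θ − θ̂), and the mean SE over all 8500 simulees. T = 50 + 10·θ is
  inferred from the θ = 2 ⇔ T = 70 anchor.
* **Seeds.** A master seed (default 1234) feeds a `SeedSequence` tree: one
  branch for the bank, one per replication, one per scenario × fraction for
  sampling and response generation. Any condition can be reproduced in
  isolation from the provenance log.

A green test establishes that *this estimator on this stated world*
reproduces the direction and approximate size of the published biases; it
does not certify agreement with any particular real item bank, nor with the
original study's exact software defaults (quadrature scheme, convergence
rules and priors of that software are unpublished — statistical, not
numerical, agreement is the goal).

## What the replication shows

With the improper one-group calibration, scenario-1 data yield slopes
inflated by ≈ the mixture SD (√2 at 50%) and person parameters overestimated
(bias shrinking as the clinical fraction rises); scenario-2 data calibrated
without weights yield location and person parameters underestimated (bias
growing with the clinical fraction); in every condition the improper
calibration reports a smaller mean SE than the proper one, i.e. measurement
precision is overestimated — consequential when the SE is a CAT stopping
rule. The proper analyses (two-group; weighted) recover item parameters and
leave person estimates biased only where the bank carries no information
(MAP shrinkage below θ ≈ −1.5).

## Limitations

* **Rare top categories.** At 25% clinical respondents in scenario 1 the top
  category of high-threshold items is observed a handful of times or not at
  all; unpenalized MML then overestimates b4 systematically (flat,
  right-skewed profile likelihood), by ~0.2–0.3 on average across the bank
  in single replicates. The published study reports near-zero mean b4 bias
  for its (unpublished) bank; that level is not reachable here without
  priors or multiple replicates, and no prior is added because the study's
  estimator used none.
* Single-replicate design: all full-scale comparisons carry Monte-Carlo
  noise; `StudyConfig(n_replications=...)` supports averaging, which the
  replication mode deliberately does not use.
* No standard errors for item parameters (none are reported in the study);
  no 2PL/nominal models; latent SDs fixed at 1; no CAT administration.
* Normal latent distributions only; skewed or unipolar traits are out of
  scope.
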