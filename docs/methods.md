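# Methods

`vmtopics` implements a mixed-membership analysis of longitudinal vaginal
microbiota profiles: latent Dirichlet allocation (LDA) on taxon count tables,
alignment of topics across model resolutions, comparison with reference
sub-community state type (sub-CST) centroids, composition prediction and
dominance-loss risk, menstrual-cycle segmentation and standardization, and
cycle-resolved association testing. This note records the models, the choices
made where the design was open, and what the synthetic cohorts do and do not
establish.

## Topic model and inference

Counts for sample *i* are modelled as a multinomial draw from the mixture
`Σ_k γ_{ik} β_{kj}` with Dirichlet priors on topic mixtures (`alpha`, default
`1/K`) and topic-taxon distributions (`eta`, default 0.01). Library size
enters the likelihood directly; no prior normalization of counts.

Inference is a blocked Gibbs sampler on the augmented model: given `(θ, β)`
the topic allocation of each (sample, taxon) count cell is multinomial, and
given the allocations `θ` and `β` have conjugate Dirichlet full conditionals.
The sweep cost scales with the number of nonzero count cells rather than with
sequenced reads, so full-length chains (default 2000 sweeps, 500 burn-in,
thinning 10) are practical at realistic library sizes (10⁴–10⁵ reads per
sample). Reported `β̂`/`γ̂` are posterior means of the smoothed allocation
counts over thinned post-burn-in sweeps.

Two numerical choices matter:

- **Warm start.** When memberships are near-deterministic the blocked sampler
  mixes slowly between modes, so the chain starts at a mode found by
  multiplicative EM (150 iterations, best of 3 seeded restarts). The sampler
  then quantifies posterior mass around that mode. Everything remains
  deterministic under the seed.
- **Canonical taxon order.** Taxa are processed in a content-sorted order
  internally, so permuting input taxon columns permutes the fitted `β`
  columns exactly (an equivariance the tests check), rather than only in
  distribution.

The log-likelihood trace of an MCMC chain is stochastic; the recorded trace is
checked for stability/improvement on average after burn-in, not monotonicity.

## Topic alignment and resolution selection

Models fitted at increasing K are connected by product weights
`W^(m,m+1)_{kk'} = (1/N) Σ_i γ^m_{ik} γ^{m+1}_{ik'}` (entries sum to 1).
Topics are organized into paths greedily, left to right: each topic attaches
to the parent with the strongest incoming column-normalized weight; among
children of one parent, the strongest continuation keeps the path id and the
rest spawn new paths (ties: larger parent mass, then lower index).

**Coherence** of a topic is the mean over *other models containing its path*
of `min(out-normalized, in-normalized)` cross-model weight between the topic
and the same-path node there. For the product method the cross-model weight
between any two models is computed directly from their `γ` matrices
(`γ_aᵀ γ_b / N`, then row/column normalized). Composing row-normalized
adjacent matrices instead would decay multiplicatively with model distance
under genuinely mixed memberships, making mean coherence decrease in K
regardless of structure; direct weights are distance-free and preserve the
defining special cases (coherence 1 under perfect nesting, normalization of
W). Topics whose path exists in no other model score 0. For transport-method
graphs (optimal transport between topic masses with Jensen–Shannon ground
cost) the composed form is kept.

**Refinement** of a topic u is `Σ_v outnorm(u→v)·innorm(u←v)` over next-model
topics: 1 when u's children draw only from u, 0.5 when children draw equally
from two parents.

The working resolution K\* maximizes mean node coherence; ties break toward
smaller K.

## Reference centroid comparison

Bray–Curtis dissimilarity `1 − Σ_j min(p_j, q_j)` labels topics by nearest
centroid, with sub-level letters collapsed to the CST family (I-A/I-B → I;
IV keeps its sub-family letter, numeric sub-levels collapse, IV-C0…C4 →
IV-C); duplicated families get `.a`, `.b`, … suffixes in decreasing topic
mass order. Samples are assigned to the centroid maximizing the Yue–Clayton
similarity `θ = Σpq / (Σp² + Σq² − Σpq)`. Taxa are harmonized onto the
centroid taxonomy by an explicit mass-preserving map; unmapped taxa pool into
`Other` with a logged warning. Matching is exact-string after harmonization —
no fuzzy matching.

## Composition prediction, stability, dominance loss

Predicted composition from topics is `p̂ = γβ`; from a sub-CST assignment it
is the centroid row. Representation error is the per-sample Bray–Curtis
between actual and predicted composition; sources are compared with a
one-sided paired t-test (refused below n = 3; identical sources give p = 0.5
by the one-sided convention).

A sample is locally *stable* when it belongs to a run of five consecutive
samples whose consecutive-pair Bray–Curtis dissimilarities are all below 0.25
(0.15/0.35 for sensitivity). The rule is consecutive-pair, not all-pairs —
the weaker reading; participants shorter than the window are entirely
unstable.

Dominance loss (next sample's total *Lactobacillus* proportion < 50%) is
predicted from the current sample's features: the γ vector with one component
dropped (sum-to-one), or one-hot sub-CST with the reference level dropped.
The logistic regression is weighted 10-fold toward the minority class and is
unpenalized. Evaluation repeats participant-grouped 80/20 splits (all of a
participant's transitions on one side, preventing leakage) with both feature
sources on identical splits; F1 uses the 0-when-no-positive-predictions
convention; sources are compared with a Wilcoxon rank-sum test on the
per-repeat F1 values. Repeats whose test split lacks a class are excluded and
logged.

## Menstrual cycles

Bleeding diaries (scores 0–3) are screened (exclude < 3 or > 30 bleeding days
per 70-day window) and segmented with a two-state explicit-duration hidden
semi-Markov model: Menses duration ~ discretized N(4, 1.5) on 1–10 days,
InterMenses ~ discretized N(24, 4) on 5–80 days; Menses emits scores
(0,1,2,3) with probabilities (0.1, 0.3, 0.4, 0.2), InterMenses (0.95, 0.05,
0, 0), so isolated spotting does not open a cycle. Viterbi decoding uses
survival mass `P(D ≥ d)` for segments truncated by either diary edge. A
numerical point worth recording: log-zero sentinels inside cumulative
emission sums must be moderate (−10⁴ here) — a huge sentinel (−10³⁰)
destroys float precision of every later partial sum and silently corrupts
the decoding.

Cycledays standardize to −18…+7 with day 0 the first day of menses: forward
index from the most recent onset wins when 0–7 (so menses days are always
0…+7), otherwise the backward index from the *next* onset applies when
−18…−1, otherwise the day is dropped. The backward anchoring reflects the
lower variability of the luteal phase.

Between-cycle agreement uses the RV coefficient
`tr(XXᵀYYᵀ)/√(tr((XXᵀ)²)tr((YYᵀ)²))` on column-centred per-cycleday means of
shared cycledays (computed via `‖XᵀY‖²_F`, which is exact), with a
row-permutation test, `p = (1 + #{RV_perm ≥ RV_obs})/(n_perm + 1)`, BH
adjusted across participants. Within-cycle change is the maximum pairwise
Bray–Curtis among renormalized per-cycleday mean compositions.

## Assay preprocessing and cyclicity testing

Metabolites: drop features missing in > 50% of samples, then samples missing
> 60% of remaining features (strict inequalities), then the generalized log
`h(x) = log₂((x + √(x² + c))/2)` with `c` the squared 5th percentile of each
feature's positive values — a closed-form variance-stabilizing transform
whose `c → 0` limit is `log₂`. Cytokines: below-LLOQ → LLOQ/2, above-ULOQ →
ULOQ, replicate medians after imputation, then natural log; assay failures
stay missing.

Cyclicity is tested against a periodic cubic B-spline basis on the 26-day
circle (4 d.f., C² continuous across the wrap between day +7 and day −18,
partition of unity — one redundant column is dropped against the intercept,
leaving 3 numerator d.f.). Continuous features use OLS with an F-test against
intercept-only; topic proportions use quasi-binomial regression with a
scaled likelihood-ratio chi-square. Constant responses give p = 1 by
convention. Batch testing applies Benjamini–Hochberg. No participant-level
random effects are fitted — a known limitation; the permutation/calibration
tests quantify the realized type-I error under the exchangeable synthetic
design, not under strong within-participant correlation.

## Host associations

Per-participant mean topic proportions (renormalized) are the unit of
analysis, avoiding pseudo-replication of dense longitudinal sampling.
Dirichlet regression uses the common parameterization `α_k = exp(X b_k)`
fitted by L-BFGS with analytic gradients; zeros are removed first by the
simplex compression `y′ = (y(n−1) + 1/K)/n` (a bijection preserving row
sums); Wald tests use the inverse numeric Hessian; a fit that does not
improve on the moment-matched start is flagged unconverged, never silently
reported. Preterm birth is tested with one logistic regression per topic
(outcome ~ intercept + mean proportion) — a joint fit is rank deficient under
the sum-to-one constraint — with BH across topics and a minimum of 10
participants.

## Synthetic cohorts: what they emulate

The generator produces cohorts with the structure the analyses assume, and
ground truth for every stage. Defaults define the standard study conditions
(300 samples: 20 participants × 15 samples; 40 taxa; K_true = 6).

- **Topics**: four near-point-mass *Lactobacillus* topics (0.93–0.95 on one
  species), one diverse anaerobe topic, and one "synonym" topic giving equal
  mass (1 − 0.4)/4 = 0.15 to four mutually exclusive genera plus a shared
  0.4 background.
- **Memberships**: participant baselines from an anchored Dirichlet
  (symmetric 0.25 plus 8.0 on a participant-specific anchor rotating over
  topics, so every sub-community is represented — mirroring deliberately
  heterogeneous cohort selection); day-to-day logistic-normal AR(1) drift on
  topic logits (ρ = 0.7, stationary sd 0.5). These values were calibrated
  once so that sub-communities are identifiable at the true resolution while
  memberships remain genuinely mixed.
- **Synonym exclusion** is participant-level: each participant carries one of
  the four genera; the kept genus absorbs the whole synonym niche mass
  (≈ 0.6), background unchanged, so one genus dominates synonym-topic
  samples, as in the phenomenon being emulated. Baseline (non-anchored)
  expression of the synonym topic is damped 10-fold: these sub-communities
  are episodic/menses-associated rather than persistent. Without the damping,
  each participant's persistent trace of their variant genus co-occurs with
  their anchor community and the likelihood prefers absorbing the genus into
  the anchor topic — a trap that misrepresents the episodic biology.
- **Menses coupling**: non-pregnant participants get semi-Markov bleeding
  diaries (cycle 28 ± 3 d, menses 4 ± 1 d, spotting rate 0.05) and a +3.0
  log-odds shift of the synonym topic on menses days.
- **Counts**: multinomial at log-normal library sizes (median 20 000,
  log-sd 0.5); no overdispersion knob in this version.
- **Assays**: cyclic features follow `amplitude·cos(2π(d − peak)/26)` with
  unit-sd noise, quantile LOQ censoring and MCAR missingness.
- **pH** is generated as 4.2 + 1.2·(1 − *Lactobacillus* fraction) + 0.4 on
  menses days + N(0, 0.15) — dominated samples centre near 4.4,
  non-dominated near 5.1, rising during menses.
- The **dominance-loss generator** draws *Lactobacillus*-anchored mixtures
  whose loss hazard is logit-linear in γ (intercept −4.5; weights 5 on the
  *L. iners* topic and 8 on the anaerobe topics), yielding ~20–25% loss among
  dominant samples.

Because the realized topic-taxon distributions differ from the template in
the synonym topic (participant-level exclusion), recovery is evaluated
against the usage-weighted *effective* β the generator records — the actual
data-generating quantity.

What passing does **not** show: robustness to overdispersed counts, taxonomic
misassignment, batch effects, irregular sampling, or within-participant
correlation structures beyond logistic-normal AR(1); the calibration results
(RV, cyclicity) hold under the generator's exchangeable designs.

## Problem sizes

Tests and the acceptance script run at desk scale chosen to finish in
minutes on one core: full-length chains (2000 sweeps) for the single
recovery fit; 300-sweep chains across K = 2…8 for resolution selection;
1000 simulations × 199 permutations for RV calibration; 100–200 replicates
for regression recovery; 100 diaries for segmentation. Thresholds are fixed
properties of the method, not tuned to these sizes.
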