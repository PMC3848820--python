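# Methods

## Model and estimation

The data are an N×R table of binary annotations yᵢʲ (missing cells allowed)
and an N×d feature table. The generative view: instance features arise from
a K-component Gaussian mixture; the hidden label follows a logistic link
pᵢ = σ(**w**ᵀ**x**ᵢ) on the features; annotator j, conditioned on the
component k that generated the instance, reports the true label with
sensitivity α_kʲ (on positives) and specificity β_kʲ (on negatives),
independently across annotators.

Fitting proceeds in stages:

1. **Mixture.** A Gaussian mixture is fitted to the features with
   scikit-learn, selecting the order K and the covariance family jointly by
   BIC over a grid (default K ∈ 1..6 × {spherical, diagonal, tied, full});
   each candidate uses several EM restarts (default 5) driven by one seed,
   covariances regularized by adding 1e-6 to the diagonal. The winning
   family tag is recorded in the model object so runs are auditable.
   Responsibilities τ_ik and hard assignments q_i = argmax_k τ_ik (ties to
   the lowest index) come from the stored parameters, with covariances
   expanded to full matrices regardless of the fitted family.
2. **Consensus loop.** Soft labels start at the majority vote
   zᵢ = mean of observed yᵢʲ. Each iteration updates, in order:
   - α_kʲ = Σᵢ z_ik yᵢʲ / Σᵢ z_ik and
     β_kʲ = Σᵢ (τ_ik − z_ik)(1−yᵢʲ) / Σᵢ (τ_ik − z_ik) with
     z_ik := τ_ik·zᵢ, sums over instances where annotator j is observed.
     The joint-responsibility definition of z_ik guarantees
     0 ≤ z_ik ≤ τ_ik, so both updates are proper weighted averages. A zero
     denominator (a component with no positive or no negative mass for that
     annotator) falls back to 0.5 and is flagged rather than raising;
     estimates are clamped to [1e-6, 1−1e-6] so no likelihood product can
     vanish.
   - the logistic prior: **w** maximizes the soft-label Bernoulli
     log-likelihood Σᵢ [zᵢ log σ(**w**ᵀ**x**ᵢ) + (1−zᵢ) log(1−σ(**w**ᵀ**x**ᵢ))]
     with an L2 penalty of 1e-4 and an intercept column appended last,
     refit from **w**=0 each iteration by L-BFGS with analytic gradients —
     a deterministic refit avoids path dependence across iterations.
   - the MAP posterior zᵢ = aᵢpᵢ/(aᵢpᵢ + bᵢ(1−pᵢ)) with the likelihood
     factors aᵢ, bᵢ taken as products over the annotators *active in the
     instance's hard component* and observed for that instance, computed in
     log space. An instance with no usable annotator falls back to its
     prior and is flagged.
   The loop stops when maxᵢ|Δzᵢ| < ε (default 1e-4) or after `max_iter`
   (default 100) iterations.
3. **Filtering.** With pruning threshold ξ (default 0.3), once the loop has
   converged every active annotator with ranking score
   S_kʲ = |α_kʲ + β_kʲ − 1| < ξ is removed from component k's active set
   Λ_k, permanently; the loop then resumes from the current zᵢ with the
   reduced sets, and the measure/prune/refit cycle repeats until a pass
   removes nobody. If a pass would empty a component, the single
   highest-scoring annotator is retained — the posterior product must stay
   defined. Filtering on *converged* scores is a deliberate design choice:
   scores measured one pass after the majority-vote initialization are
   dominated by initialization noise (every annotator's score is inflated
   by the correlation with its own vote inside the majority), and in
   novice-dominant panels a single-pass check deactivates near-random
   choices irreversibly; at the fixed point of the current active sets the
   expert/novice gap is unambiguous. ξ = 0.3 separates "random" (S ≈ 0)
   from "informative" (experts S ≥ 0.5 in the reference conditions); the
   default decision threshold on z is γ = 0.5 (symmetric loss).
4. **Orientation.** The likelihood is invariant under the global flip
   (z → 1−z, α ↔ 1−β, **w** → −**w**), and when informative annotators are
   rare the majority-vote initialization is too weak an anchor — the loop
   can converge to the mirror solution in which good annotators appear as
   systematic inverters. The engine therefore reports the representative of
   the mirror pair in which the active annotators are on average
   informative (mean of α+β−1 over active cells ≥ 0). S is flip-invariant,
   so filtering decisions are unaffected; all four algorithms apply the
   same convention, preserving the exact reduction identities
   AEFN(ξ=0) ≡ GMM-MAPML and GMM-MAPML(K=1) ≡ MAP-ML.

MAP-ML is the same loop with τᵢ₁ ≡ 1 and no mixture fit; GMM-MAPML is the
loop without the filtering stage; majority voting thresholds the soft vote
at 0.5 with ties resolved to 0.

## Synthetic data generator

The generator mirrors the model's assumptions so that recovery tests are
well-posed. Defaults (the reference study conditions): N=2000 instances,
d=2 features, K=2 components with identity covariances and means ±3 on the
first feature axis, equal weights; hidden labels from the logistic link with
**w** = (0, 1.5, 0) — the label signal rides on the *second* feature, so
class balance is ≈50/50 inside every component and per-component α/β are
estimable. A `component_rate` mode draws labels at fixed per-component
positive rates instead, as a deliberate misspecification stress test.
Annotations are Bernoulli draws from each annotator's per-component (α, β);
optional missingness masks cells uniformly at a given rate, restoring one
random cell in any row that would lose all its labels (the package requires
at least one observed label per instance).

Two panel builders cover the regimes of interest:

- `make_panel(n_experts, n_novices, k)` — globally-typed annotators:
  experts draw α, β ~ U(0.8, 0.95) independently per component
  (S ∈ [0.6, 0.9]); novices draw α ~ U(0.45, 0.55) with β = 1−α, pinning
  S = 0 exactly so the filter's target population is unambiguous.
- `make_specialist_panel(n_annotators, k)` — component-dependent quality:
  annotator j ≤ K is expert-grade in component j only and novice-grade
  (S = 0) elsewhere; the rest are novices everywhere. Each component then
  holds exactly one expert-grade annotator and n−1 uninformative ones.
  This is the regime the component-conditioned models exist for: under
  globally-typed panels the component model is the global model plus
  estimation noise, and the comparison between them is uninformative.

What the generator does **not** emulate: correlated annotator errors
(real predictor panels share training data and features), instance-specific
difficulty, adversarial or colluding annotators, and annotators whose
quality varies continuously rather than by mixture component. Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to these violations.

## Replicated studies and problem sizes

`aefn.experiments` packages three seeded studies, each 20 replicates at
N=2000, K=2, R=10 (seeds spawned from one base seed via SeedSequence):

- **parameter recovery** — globally-typed panels (2 experts + 8 novices);
  mean absolute error of the retained annotators' (α, β) estimates after
  matching fitted to generating components by maximal-overlap assignment
  (typical MAE ≈ 0.015–0.02, experts mildly inflated by the
  self-confirmation of the converged posterior);
- **filtering + method ordering** — specialist panels; records whether each
  component keeps its expert and sheds ≥8/9 novices, and the exact AUC of
  MV / MAP-ML / GMM-MAPML / AEFN posteriors against the simulated truth;
- **annotation-source comparison** — the 40%/60% protocol: fit on the 40%
  split (stratified by true label), recommend the top-scoring annotator per
  component, then compare downstream logistic classifiers trained on labels
  from a random annotator / the recommended annotator / the truth, by
  stratified 5-fold cross-validation on the 60% split (folds whose training
  labels are single-class are skipped with a warning).

The studies fix the mixture search at the known K with the full-covariance
family and 3 restarts — the model-selection grid is exercised separately in
the unit tests — which keeps each full study under ~20 s on one core
without changing the measured quantities.

## Disorder application layer

Each residue of a protein becomes an instance; each existing per-residue
disorder predictor becomes an annotator. Features are 20-dimensional,
computed from a 21-residue window centred at the position (truncated at the
sequence ends rather than padded): entries 1–19 are the relative
frequencies of the amino acids A,C,D,…,W in one-letter alphabetical order —
tyrosine's frequency is implied because composition is closed, and any
single drop is information-equivalent; the choice is recorded in the
feature names — and entry 20 is the Shannon entropy of the 20-letter window
composition normalized by log 20, a standard low-complexity surrogate in
[0, 1] (low-complexity regions tend to be disordered). Nonstandard letters
are tolerated in sequences but excluded from the counts; an all-nonstandard
window yields a zero vector with a warning.

Evaluation applies two conventions: disorder segments shorter than 4
residues are excluded from the evaluation mask (guarding against
experimental uncertainty in the reference annotations) while all residues
participate in the unsupervised fit; and positions are partitioned into
N-terminus / internal / C-terminus, the termini being the first and last
⌈0.2·L⌉ residues (a position satisfying both rules on a very short sequence
counts as N-terminus, keeping the partition exact). Coordinates are 1-based
throughout the residue tables. Metrics are the balanced accuracy
(sensitivity+specificity)/2 and the exact Mann–Whitney AUC
P[s⁺ > s⁻] + ½P[tie] — a rank statistic, so no threshold grid is involved
and any strictly monotone rescaling of the scores leaves it unchanged.

## Numerical and interface choices

- All randomness in a run flows from one integer seed (mixture restarts,
  simulation draws, splits, folds); identical configs give byte-identical
  outputs.
- α, β, and prior probabilities are clamped to [1e-6, 1−1e-6]; likelihood
  products are accumulated in log space.
- Ties: hard component and recommended annotator resolve to the lowest
  index; an exact majority-vote tie resolves to label 0.
- Missing labels are first-class: every sum or product over annotators
  skips unobserved cells, and an instance whose active annotators are all
  unobserved is estimated from the prior alone (flagged in the result).
- Result files are plain text (TSV + JSON) written with 17 significant
  digits, so write→read round-trips reproduce every float exactly.

## Known limitations

- Binary labels only; no multi-class or ordinal extension.
- Annotator errors are assumed conditionally independent given the true
  label and component; correlated panels (e.g. predictors sharing training
  data) will make the consensus overconfident.
- Filtering is permanent by design; an annotator unfairly pruned early in a
  small component cannot return. The never-empty safeguard bounds, but does
  not eliminate, the cost of a wrong removal in degenerate panels.
- The orientation convention assumes the active panel is informative on
  average; a panel dominated by systematic inverters would be reported
  flipped (their high S still makes them useful — their votes are simply
  read in reverse — but the labels would need external anchoring).
- The logistic prior is linear in the supplied features; strongly
  non-linear label structure should be handled by feature engineering
  before fitting.
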