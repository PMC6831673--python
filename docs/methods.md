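# Methods

`fuzzyforests` implements a two-stage variable-screening procedure for
high-dimensional survey data whose predictors are strongly inter-correlated,
followed by the survey-weighted logistic validation step that such screens
are usually paired with, and a synthetic survey generator that makes every
stage testable without access to restricted survey extracts.

## The screening model

Random-forest permutation importance is biased when predictors are
correlated: members of a correlated group inherit importance from each other
and crowd independent predictors out of the top ranks.  The two-stage screen
addresses this directly.

**Stage 1 — module detection (unsupervised, deterministic).**
Features are connected by an unsigned soft-threshold adjacency
`a_ij = |cor(x_i, x_j)|^beta` (Pearson).  The adjacency is converted to a
topological-overlap dissimilarity

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l_ij = sum_{u != i,j} a_iu a_uj

with connectivity `k_i = sum_{j != i} a_ij`, and `1 - TOM` is clustered with
average linkage.  The tree is cut statically, clusters smaller than
`min_module_size` stay unassigned (label 0), modules whose eigengenes (first
principal components of the standardized module block, unit-norm, sign-fixed
to correlate non-negatively with the module mean) correlate above
`merge_similarity` are merged iteratively, and finally unassigned features
whose absolute correlation with some module eigengene ("module membership",
kME) reaches `reassign_threshold` are attached to that module.  The outcome
never enters stage 1.

**Stage 2 — module-wise selection (supervised).**
Within every module — including the pseudo-module of unassigned features,
which is screened rather than discarded precisely because independent
predictors are what correlation bias penalizes — a recursive-feature-
elimination forest keeps the top `max(1, ceil(keep_fraction * size))`
members by out-of-bag permutation importance (VIM), dropping the lowest
`ceil(drop_fraction * current)` per round and truncating the final round by
rank.  Survivors from all modules are pooled into one final elimination
forest and the top `number_selected` features are reported.  VIM is the raw
(unscaled) mean decrease in OOB accuracy when a feature is permuted within
each tree's OOB sample; ties in rank break lexicographically by name.

**Validation.** A logistic regression with the survey weights entering the
pseudo-log-likelihood multiplicatively,
`sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`, fit by IRLS on the
selected features plus forced adjusters, with odds ratios and z-based Wald
limits `exp(beta +/- 1.96 se)`.  The variance is the weights-only sandwich
`A^{-1} B A^{-1}` with `A = X' diag(w p (1-p)) X` and
`B = sum_i w_i^2 s_i s_i'` — a with-replacement approximation that ignores
strata/PSU structure, so intervals are modestly narrower than full
design-based Taylor-linearized ones.  Weights are normalized to mean one
before fitting; points estimates are invariant to weight rescaling.
Held-out evaluation reports accuracy at a 0.5 threshold and the
Mann-Whitney AUC (ties get half credit).  Both the logistic's held-out
accuracy and the final forest's are reported, since "the model's accuracy"
can reasonably mean either.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `power` (beta) | 7 | soft-threshold exponent; the standard unsigned-network choice at survey scale. A scale-free grid search is available (`candidate_powers`) but off by default: on block-structured survey data the scale-free R² path is non-monotone noise and its argmax lands on extreme powers that crush weakly correlated modules. |
| `cut_height_fraction` | 0.98 | static cut at this fraction of the dendrogram's merge-height *range*. TOM merge heights crowd toward 1 (the maximum is essentially always ~1.0), so a fraction of the maximum is degenerate — it falls below every merge and yields no modules. Within-module merges complete by ~0.99 of the range while cross-module joins sit in a tight plateau at the top, so a high range-relative cut isolates exactly that band. |
| `min_module_size` | 5 | smaller clusters stay unassigned and are screened as pseudo-module 0. |
| `merge_similarity` | 0.5 | eigengene correlation above which modules merge ("more than 50 percent similarity"). |
| `reassign_threshold` | 0.3 | minimum |kME| for attaching a straggler to a module; independent features sit far below it (|r| ~ n^{-1/2}) while true module members sit near sqrt(rho). |
| `keep_fraction` | 0.35 | per-module survivor share. |
| `number_selected` | 20 | final selected-set size. |
| `drop_fraction` | 0.25 | per-RFE-round elimination share; geometric descent with exact terminal truncation. |
| `ntree` | 50 | trees per forest. Sized with `sample_fraction` for repeated desk-scale screening runs: half-size bootstraps plus a 5-observation leaf floor and an OOB evaluation cap of 500 rows per tree give stable importance *ranks* at n in the low thousands while keeping a full two-stage run near ten seconds on one core. With mtry = ceil(sqrt(p)) every feature is evaluated many times per tree at these p, so each parameter has ample opportunity to enter the model; raise `ntree` for publication-grade importance values. |
| `mtry` | ceil(sqrt(p)) | candidate features per split; `mtry_grid` enables an OOB-accuracy grid pick in the final forest. |
| `n_permutations` | 1 | permutation repeats averaged per tree; VIM is already averaged over trees and OOB rows. |
| `weighted_bootstrap` | off | survey weights stay out of the forests by default — they belong to the validation model; a weighted-bootstrap option exists. |

Determinism: stage 1 contains no randomness; every stage-2 seed is derived
from the master seed through a named SHA-256 counter scheme
(`derive_seed(master, "module", k)` etc.), so module order, repetition
order, and parallelism cannot change results, and the same inputs and seed
reproduce results byte-for-byte.

## The synthetic survey

The generator emulates the structure of a large multilingual health survey
(the California Health Interview Survey is the template) at desk scale:

- **Block-correlated items.** One latent factor per module:
  `x_j = sqrt(rho) f_k + sqrt(1-rho) eps_j`, so within-module correlation is
  exactly `rho` (defaults: five modules of 40 items, rho = 0.8/0.7/0.6/0.7/0.5)
  plus 30 independent items.
- **Planted signals.** Five coefficients of 1.5 — three inside modules, two
  independent — chosen so the realized Bayes accuracy is ~0.86, the held-out
  accuracy regime this class of screen is reported to operate in.
- **Interview language.** A 7-level factor with CHIS-like shares (the larger
  2014-wave non-English mix) and one very rare level with expected count 1
  at n = 2000 — the level that destabilizes a logistic model and must be
  deleted, which `drop_rare_language` (min_n = 2) does without naming any
  language.  Level effects on the log-odds sit in the upper part of the
  odds-ratio range such surveys exhibit (Spanish analogue -3.0 ~ OR 20;
  ORs from ~3 to ~90 are reported for real interview-language contrasts);
  weaker effects would be washed out by the planted features' linear-
  predictor spread (sigma ~ 3.3) and no estimator could find them.
- **Outcome.** A Bernoulli draw from the logistic model, then mapped to a
  5-level self-rated-health item (Excellent/Very Good/Good vs Fair/Poor)
  that recodes back to the binary outcome exactly.
- **Weights.** i.i.d. lognormal(0, 0.5): positive, right-skewed,
  mean-normalizable — the shape of survey weights without any design
  structure.

What the generator does *not* emulate: multi-stage sampling (strata, PSUs,
raking), item nonresponse, Likert discreteness (an optional quantile cut
exists), or real CHIS marginals.  Passing tests therefore demonstrate the
algorithmic properties of the screen — module recovery, planted-signal
recovery, null calibration, the correlated-decoy advantage — not calibration
to any real survey's estimates.

In the forest stage a nominal variable enters as a single integer-coded
column (as factors do in the R forest lineage) so a multi-level factor
competes for selection as one feature; in the regression design it expands
to reference-coded indicators against its first-listed level.  Splitting a
factor into indicators inside the forest dilutes its importance across
levels and can hide a genuinely strong factor behind correlated decoys.

## Numerical choices and degenerate inputs

- IRLS converges at max |delta beta| < 1e-8 (100 iterations cap); linear
  predictors are clipped at ±30 and fitted probabilities at 1e-10 during
  iteration.  Non-convergence with a coefficient beyond |beta| > 15 raises a
  `SeparationError` naming the term; the pipeline responds by deleting that
  factor level's respondents from the validation model (recorded in the
  manifest), which is the standard survey-analysis response to a
  weakly-identified rare level.  Separation on a non-factor term propagates.
- The scale-free fit index returns R² = 0 with a `degenerate` flag when all
  connectivities are equal; empty histogram bins are skipped.
- Features are clustered in lexicographic-name order, which both fixes
  tie-breaks and makes `build_network` exactly permutation-equivariant.
- A singleton module's eigengene is its standardized column
  (variance explained = 1); zero-variance features are rejected by name
  before any network is built.
- Published-style percentages round half away from zero to two decimals.
- Unseen factor levels anywhere in scoring raise an error naming the level;
  missing condition indicators are an error, never imputed silently.

## Known limitations

- The static range-relative cut recovers modules whose within-correlation is
  roughly >= 0.5 at power 7; markedly weaker modules (rho <~ 0.4) fragment
  and fall back to the unassigned pool (where their members are still
  screened).  Dynamic tree cutting is deliberately out of scope.
- Sandwich intervals ignore the sampling design; replicate-weight and
  stratified Taylor variances are out of scope.
- Binary outcomes only; no regression forests, no conditional-inference
  trees, no importance p-values.
- The forest defaults favor repeated screening runs over minimum-variance
  importance values; single definitive runs should raise `ntree`.
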