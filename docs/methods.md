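# Methods

## The measurement problem

Standard mental-health assessment asks respondents to compress their state
into numeric ratings. The alternative implemented here elicits free
language — five descriptive words summarising an emotional narrative —
and quantifies it with a distributional semantic model, so that the two
response modes can be compared on the same classification task: recover
which of four states (harmony, satisfaction, depression, anxiety) a
narrative describes. Alexithymia, the trait difficulty of identifying and
describing one's own emotions, enters twice: the narrator's alexithymia
may make a narrative harder to classify, and the evaluator's alexithymia
may make their summaries less accurate.

## Semantic model

Word meaning is estimated by latent semantic analysis over a corpus of
short word responses, each response one context:

1. **Co-occurrence.** C[i,j] = number of contexts containing both word i
   and word j; C[i,i] = number of contexts containing i. Counting is
   context-level: a word repeated inside one response counts once, and a
   pair co-occurring in several responses counts once per response.
2. **Compression.** The table is transformed elementwise by log(1 + c)
   and decomposed by truncated SVD. "Log plus one" rather than
   log(c) + 1: the latter is undefined on the zero cells that dominate a
   sparse co-occurrence table. Word i is row i of U·S on the first
   k = 300 dimensions (variance-weighted; raw-U is available via
   `weighting="u"`), renormalised to unit length. When the matrix rank is
   below k, k is clamped with a warning.
3. **Determinism.** SVD sign indeterminacy is resolved by forcing the
   largest-magnitude entry of each singular vector positive; two builds
   of the same corpus are bit-identical.
4. **Response vectors.** A response embeds as the normalised sum of its
   words' vectors. Tokens are lowercased and stripped of surrounding
   punctuation; out-of-vocabulary words are skipped and counted, and a
   response with no known word is excluded with a logged warning rather
   than imputed. No frequency floor, stop list or stemming is applied.

## Classification

Multinomial logistic regression maps features to the four states. A small
L2 penalty (λ = 1e-4) is always present because plain maximum likelihood
diverges on separable data; the fixed class order (harmony, satisfaction,
depression, anxiety) breaks exact prediction ties.

Evaluation is 10-fold cross-validation **grouped by narrative**: the
distinct narrative ids are shuffled by the seed and dealt round-robin
into folds, so all responses tied to one narrative — the narrator's own
Phase-1 response and every Phase-2 evaluation of it — share a fold, and a
model is never scored on a narrative it trained on. Training pools
Phase-1 and Phase-2 rows; accuracy is computed on Phase-2 rows only
(configurable via `eval_phase`).

Inside each training fold a nested grouped 5-fold CV selects the number
of leading semantic dimensions from a geometric grid
{2, 3, 5, 8, 12, 18, 27, 40, 60, 90, 135, 200, 300} (clipped to k), by
inner accuracy with ties to the smaller count. The grid spans the few-to-
hundreds range where such selections typically land without exhaustive
search. Rating-scale features (the 4 totals, or the 26 items) are
z-scored with training-fold statistics; semantic dimensions are left raw,
being already variance-ordered by the SVD. The combined feature family
concatenates the selected leading dimensions with the 4 z-scored totals.

## Scale regression

The same nested grouped CV drives ordinary least squares from response
embeddings onto each empirical scale total, with the inner criterion the
out-of-fold Pearson r (the quantity reported). Predictions are raw linear
outputs, deliberately not clipped to the scale range. The final predictor
refits on all rows at the modal fold-selected dimension count (ties to
the smaller). Rank-deficient designs fall back to a tiny ridge with a
warning.

## Evaluation statistics

Confusion matrices are predicted-by-true counts in the fixed class order.
Per class, with TP the diagonal cell, FP the rest of the predicted row,
FN the rest of the true column and TN the remainder: sensitivity
TP/(TP+FN), precision TP/(TP+FP), specificity TN/(TN+FP), accuracy
(TP+TN)/N, F1 the harmonic mean of precision and sensitivity. A zero
denominator makes the metric *undefined*, carried as NaN and rendered
"–", never as 0. The support-weighted mean of sensitivities equals
overall accuracy exactly (property-tested).

Two classifiers' correctness proportions are compared by a Pearson χ² on
the 2×2 correct/incorrect table without continuity correction; the φ
effect size is √(χ²/N), where N defaults to the table total but can be
supplied explicitly so that an effect size printed under a different N
convention is reproducible from the printed statistics. Group means are
compared with pooled-variance t-tests (df = n₁+n₂−2), variances with
two-tailed variance-ratio F-tests, and associations with product-moment
correlations; Bonferroni correction flags pᵢ ≤ α/m.

## Word clouds

Each vocabulary word, embedded as its own unit vector, is scored by a
trained model: the class logit for a classifier, the predicted scale
value for a regression. Clouds are the top 25 words per target, ties
broken by corpus frequency then lexicographically, with frequency
attached for size-coding; output is a ranked table, rendering being
cosmetic. The significance of a word's score is assessed against a
label-permutation null (default 1000 permutations; p = (1+b)/(B+1)) with
Bonferroni correction across the vocabulary — chosen as the most
assumption-free construction since no parametric null is natural for
model-projected word scores. A warning reports when the permutation
count cannot resolve the Bonferroni threshold. The alexithymia ×
depression clouds split records at PAQ 68 and at the PHQ-9 sample median
(ties low; the split value for PHQ-9 is not externally specified) and
score words with a multinomial model over the four cell labels.

## Rating scales and stratification

PHQ-9 (9 items, 0–3), GAD-7 (7, 0–3), SWLS and HILS (5 each, 1–7) and
PAQ (24, 1–7) are scored as plain sums; no reverse keying is applied
(callers pre-orient items). Records with missing or out-of-range items
are excluded with a logged warning, not imputed. Alexithymia groups use
PAQ ≤ 68 → low, matching the published split; the even-n sample median is
floored to an integer so a reproducible integer threshold results.

## Synthetic data

The generator emulates the study design, not its surface text:

- **Vocabularies.** 150 synthetic tokens per emotion; harmony and
  satisfaction share 30% of their vocabularies, other pairs 5%,
  reflecting the closeness of the two positive states. Within a
  vocabulary, draws are Zipf-weighted (exponent 1.0) for realistic
  frequency skew.
- **Corpus.** 7088 responses of five words each, balanced over emotions,
  with 20% word noise — the scale of the reference corpus, though with a
  deliberately smaller vocabulary (hundreds, not thousands of unique
  words) to keep the SVD light.
- **Phase 1.** 116 narrators, conditions balanced round-robin. PAQ totals
  are drawn from N(68, 20) truncated to [24, 168], so the published split
  threshold is typical. Narrators above the threshold draw words at noise
  0.40, below at 0.20 — encoding the direction that high-alexithymia
  authors produce less condition-typical language.
- **Scales.** Item values are rounded draws from a normal centred at the
  scale's lower-quartile point, shifted by 0.35 item units on the
  condition-congruent scale, SD 1.25, clipped to bounds. These values
  were fixed to reproduce the reported regime in which rating scales
  classify only modestly above the 25% chance level while words classify
  about twice as well; an early stronger setting made scales *more*
  informative than words, contradicting the emulated findings, and was
  replaced once.
- **Phase 2.** 232 evaluators, each assigned one narrative round-robin.
  Their words and scales are regenerated from the narrative's condition
  with noise set by the *narrator's* PAQ group; the evaluator's own PAQ
  is independent of difficulty (the evaluator-side null). Narrative ids
  are preserved for grouped CV.

What the generator does not emulate: real narrative text, the true
vocabulary size (~6.6k words), item-response measurement models,
inter-item correlation structure within scales, and participant
exclusion behaviour. Passing tests therefore demonstrate that the
pipeline recovers planted structure of the kind the design assumes — not
that the empirical effect sizes would replicate on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced problem sizes chosen
as the package's own desk-scale defaults: stochastic calibration checks
use 80 narrators / 240 evaluators, a 1000-response corpus and a k = 40
space; the default-conditions contrasts run the full generator defaults
(7088-response corpus, k = 300, 10 outer × 5 inner folds) averaged over
three seeds. All randomness flows from explicit integer seeds; repeated
runs are byte-identical. lbfgs fits that hit the iteration cap raise a
convergence error rather than returning silently; folds whose training
pool lacks a class log a warning and fit on the remaining classes.

## Known limitations

- The directional alexithymia contrast (low-PAQ narratives classified
  more accurately) is noisy at small n; single small-sample runs can
  flip sign, which is why directional checks aggregate over seeds.
- The permutation screen refits the scoring model per permutation; for
  multinomial targets this is expensive and is typically run with a
  reduced permutation count.
- Undefined metrics propagate as NaN; downstream consumers must treat
  them as "not computable", not zero.
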