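# Methods

This note documents the model of the data that `searchtrace` implements,
the choices that were genuinely open, and what the synthetic cohorts do and
do not establish.

## Windowing model

All analysis units are half-open 28-day windows `[start, end)` of a
participant's query stream. The admission instant belongs to the
hospitalization, never to the preceding window. Internally "1 month" is
quantified as 28 days (and "2 months" as 56) so that the gap rules and the
window length share one exact arithmetic; `month_days` is configurable.

* **Diagnostic windows** end at local midnight of the first admission.
  Cases with no queries in that window are excluded with an explicit
  notice, never silently.
* **Control windows** for healthy volunteers start at a uniformly drawn
  calendar day such that the window fits inside the archive span, redrawn
  (bounded at 100 draws) until at least one query falls inside. The draw is
  seeded per participant, and the 10-iteration resampling utility
  (`repeat_control_sampling`) re-draws every control to check that results
  do not depend on any particular placement.
* **Relapse windows**: illness = the 28 days before each admission after
  the first, skipped when under `month_days` have passed since the previous
  discharge; health = the 28 days after each discharge, requiring at least
  `2 × month_days` before the next admission, and — after the final
  hospitalization — at least 28 days of remaining archive. The 2-month rule
  gates only the health window; the illness window has its own 1-month
  rule. Health windows after the final discharge are included: observed
  cohorts show more health than illness periods, which is only possible if
  post-terminal discharge periods count. No relapse window (including its
  4-day histogram lookback) may contain data prior to the first admission.
* Windows containing zero queries are dropped with a notice rather than
  zero-filled: an off-line participant contributes no linguistic signal and
  would make every temporal statistic degenerate.

## Feature definitions

The 123 features and their blocks are listed in the README. Decisions worth
recording:

* **Query length is a word count** (the tokenizer's token count), not
  characters, matching the lexicon-analysis convention and the "searches
  consist of fewer words" phenomenology the features are meant to capture.
* **4-day histograms span a 32-day lookback** from the window end so that
  the eighth bin ("31–28 days prior") exists; the hourly histograms and the
  scalar totals use the 28-day window itself. Windows carry the extra four
  lookback days explicitly. The day index of a query is
  `floor((end − t) / 86 400 s)` and its bin is `day // 4`.
* **Derivatives run oldest→newest**, so activity declining toward the
  anchor produces a negative mean first difference.
* **Population (divide-by-n) SDs** everywhere; degenerate statistics (0 or
  1 observations) are 0 by convention, so empty windows yield all-zero
  vectors rather than NaNs.
* **Standardization is fit on training folds only** inside cross-validation
  and applied to the held-out rows — fitting on all rows would leak label
  information through the feature scales. Lexicon proportions are already
  normalized by the window's word volume and pass through unscaled;
  zero-variance columns map to 0.
* Tokenization lowercases, splits on anything that is not a letter or an
  apostrophe, and drops purely numeric residues. English-specific
  tokenization and richer text features (n-grams, embeddings) are out of
  scope.

## Lexicon

The 51-category dictionary format is the LIWC `.dic` dialect: a `%`-framed
header of numbered categories, then `word<TAB>index…` entries where a
trailing `*` marks a prefix stem. Matching gives exact entries precedence
over stems, and the longest stem wins. A token may belong to several
categories (the category graph is hierarchical: e.g. an anxiety word is
also a negative-emotion and affect word), so profiles need not sum to 1.
Proportions are reported on the 0–1 scale; multiply by 100 to compare with
tools that report percentages.

The proprietary LIWC dictionary cannot be shipped; the package includes an
open 51-category fixture (`data/fixture51.dic`) whose category labels match
the standard 2007-era inventory for every category the analysis discusses
(anger, anxiety, hear, percept, bio, health, sexual, sadness, positive
affect, inhibition, relative, inclusive, quantifier, preposition, insight,
indefinite pronoun, …), each populated with at least ten common words. Any
user-supplied `.dic` with 51 categories is accepted, and toy dictionaries
load with `expected_categories=None`.

## Classifiers and evaluation

Three scikit-learn classifiers are evaluated: RBF-kernel SVM, random
forest, and gradient boosting. Cross-validation is stratified 5-fold;
within each fold a 25% inner held-out split of the training rows selects
hyperparameters by AUC from small fixed grids (RF: `max_depth ∈ {None, 8}`
at 200 trees; SVM: `C ∈ {0.5, 2, 8}`; GB: `max_depth ∈ {2, 3}` at 100
trees, learning rate 0.1 — recorded per run in the manifest). AUC uses the
model's continuous output (probability or decision-function value). Metrics
are computed per fold and averaged, never pooled; a fold whose test rows
contain one class has no defined AUC and is excluded from the mean with a
warning. F1 is reported for the clinical class (SSD / illness). No
resampling corrects class imbalance — AUC, the primary metric, is
insensitive to it.

For the relapse task, folds are grouped by participant by default so that
no participant's windows appear in both train and test (identity leakage
would otherwise inflate performance); pass `groups=None` for the ungrouped
behavior.

All randomness (fold shuffling, inner splits, estimator seeds, control
placement, permutation streams) derives from one master seed through named
SHA-256 substreams (`model.subseed`), so every pipeline output is
byte-reproducible.

## Permutation importance

Importance of feature *j* is `AUC(baseline) − mean over n_repeats shuffles
of AUC(X with column j permuted)`, computed on each fold's validation rows
with that fold's fitted model, then averaged over folds. `n_repeats`
defaults to 10, balancing Monte-Carlo noise against desk-scale runtime; the
permutation stream is drawn feature-major from a single seeded generator so
an independent per-repeat loop reproduces it exactly. Ties in mean
importance break by feature name. The direction annotation ("higher/lower
in SSD") comes from class-conditional means of the raw feature, not from
the model — with nonlinear kernels, permutation importance measures
sensitivity, not a signed linear effect, and that limitation is inherited
here.

## Synthetic cohorts

The generator emulates the data-generating process the analysis assumes:

* **Volume**: per-day query counts are Poisson with rate
  `base × group × frailty × state`. The base rate is 11.9 queries/day (a
  control's 28-day window then averages ≈ 333 queries); participant frailty
  is mean-one lognormal with σ = 0.77, reproducing the heavy between-person
  dispersion (SD ≈ 0.9 × mean) seen in real archive volumes. The case
  baseline multiplier is 0.333 and the illness-state multiplier (28 days
  before any admission) is 1.74, so the *observed* case/control ratio in
  diagnostic windows is 0.58 and the illness/health ratio within cases is
  1.74 — both observed contrasts hold simultaneously only with this
  factorization.
* **Timing**: hour of day is drawn from a 24-weight circadian profile
  (night trough, evening peak); the process is stationary across the year —
  seasonality is deliberately not modeled, which is one reason control
  windows are randomly placed.
* **Length**: query word counts are `1 + Poisson`, mean 3.5 words, with a
  mild per-participant length frailty (σ = 0.15) and an illness-state
  length multiplier of 0.8 ("fewer words" during illness).
* **Content**: words are sampled from the closed fixture vocabulary by
  per-category weights (function-word categories dominate). Case trait
  shifts reduce relative/inhibition/quantifier/positive-affect/anxiety/
  preposition/inclusive/insight weights (×0.5–0.7); illness-state shifts
  increase sexual/hear/bio/percept/anger/indefinite-pronoun (×1.5–2) and
  reduce health/sadness (×0.5). The `truth` bookkeeping records which
  categories were shifted for each task contrast.
* **Calendars**: cases receive 1–4 hospitalizations (mean ≈ 2.4) with
  gamma-distributed gaps (mean 120 days, shape 3) and uniform 7–28-day
  stays; the default cohort is 72 cases and 128 controls over a 365-day
  archive span.

Effect magnitudes are calibrated to observed *volume ratios*, not to any
published classifier performance — per-feature effect sizes in real
cohorts are unknown. Consequently the synthetic cohorts separate much more
cleanly than real data (cross-validated AUCs near 1 at the defaults), and
passing pipeline tests demonstrate correctness of the machinery (windowing
rules, normalization, leak-free evaluation, importance attribution), not
clinical performance. The generator also omits linguistically realistic
query text, seasonality, non-stationary vocabularies, and archive gaps
caused by signed-out searching.

## Numerical and degenerate-input conventions

Empty archives raise an explicit empty-archive signal at parse time rather
than passing silently; malformed JSON errors carry the byte offset. Empty
windows yield all-zero feature vectors when constructed directly but are
dropped by the windowing stage. Zero-SD feature columns standardize to 0.
Timestamps are stored timezone-aware and binned in the archive's own
offset, since circadian features are meaningless in UTC when the
participant lives elsewhere; the parser can re-anchor to a fixed offset via
its timezone policy. Browser-history ("Visited …") records are parsed and
kept in the archive but excluded from feature extraction by default
(`SearchArchive.filtered`), because the feature definitions are stated over
search queries; whether browse records should contribute is genuinely
unsettled and the toggle is exposed.

## Problem sizes

The test suite and acceptance script run cohorts of n = 200 participants
(null calibration: 20 label permutations × 3 models; signal recovery: 10
seeds), n = 500 for mean-tracking checks, and smaller hand-built calendars
for every windowing rule — sizes chosen to give stable Monte-Carlo
statistics at desk scale.
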