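# Methods

## Task and model

Drug name recognition is treated as sentence-level sequence labeling.
Every token receives one tag from the BILOU inventory over the four entity
types *drug*, *brand*, *group*, *no-human* — 4 × 4 + 1 = 17 tags.  BILOU is
preferred over BIO because it distinguishes unit-length mentions (U) and
entity-final tokens (L), which carry most of the morphology signal for drug
names.  Mentions must be contiguous and non-overlapping: one tag per token
cannot represent nested or discontinuous annotations, so those are rejected
with an error rather than silently mangled.

The tagger is a linear-chain conditional random field over binary indicator
features:

    p(y | x) ∝ exp( Σ_t W[feat(x,t), y_t] + Σ_t A[y_{t-1}, y_t]
                    + b_start[y_1] + b_end[y_T] )

Training minimizes the negative conditional log-likelihood plus an L2
penalty `c2 · ‖θ‖²` with exact forward–backward gradients and L-BFGS.  The
objective is convex and the optimizer has no stochastic component, so
training is bit-for-bit deterministic for a fixed corpus and configuration.
The implementation is self-contained (`drugner.crf`): parameters are a
dense (features × labels) emission matrix, a (labels × labels) transition
matrix, and start/end boundary biases; decoding is Viterbi.  `c2` is the
single training knob; its default grid {0.5, 0.6, …, 1.5} is searched by
sentence-level K-fold cross-validation (default 10 folds) scored by strict
entity F1, with ties broken toward the smaller (stronger) penalty.

## Feature templates

Sixteen singleton templates (f1–f16) are instantiated at every offset of
the 5-token window (−2…+2); out-of-range positions carry `__BOS__`/`__EOS__`
sentinels so edge tokens have the same feature arity as interior ones.

Decisions the template definitions leave open, and how they are resolved:

* **Orthographic class (f4).**  Precedence order All-capitalized →
  Is-capitalized → All-digits → Alphanumeric → Other; exactly one class per
  token.  "Alphanumeric" is read as *contains both letters and digits*,
  symbols allowed (`interleukin-2` qualifies) — this is an interpretation,
  flagged here because a digits-and-letters-only reading is also
  defensible.  The hyphen flag is a second f4 string (`hyphen:Y/N`) rather
  than a separate template, keeping the registry at 16; conjunction members
  referencing f4 use the class label only, so per-token conjunction counts
  stay exact.
* **Affixes (f9–f14).**  Prefix/suffix of length 3, 4, 5.  Tokens shorter
  than an affix length omit that feature entirely (no padding): a padded
  affix would collide with genuine short affixes and add nothing.
* **Word shapes (f15, f16).**  Character classes upper→X, lower→x,
  digit→0, other→O; the brief variant collapses runs.  Characters are
  classified by Unicode case predicates, so non-ASCII letters map to X/x.
* **POS and chunk (f2, f3).**  Any tagger satisfying the contract (one POS
  and one chunk label per token, deterministic) can be plugged in.  The
  bundled default is a deterministic rule-based tagger: a closed-class
  lexicon plus suffix rules for POS, and a simple noun-phrase / verb-phrase
  chunker over those tags.  It is a first-class component of this package,
  adequate for the synthetic corpus; for real biomedical text a trained
  tagger should be attached through the same contract.
* **Dictionaries (f5–f7).**  Case-insensitive per-word membership: a token
  matches if it equals a single-word term or any whitespace-delimited word
  of a multiword term, since the feature is defined per word, not per
  span.  Three dictionary slots mirror the three-lexicon setup common in
  DNR systems.
* **Embedding clusters (f8).**  Word vectors (word2vec text format) are
  clustered by k-means (k-means++ init, 10 restarts under one seed,
  tol 1e-4, max 300 iterations); the cluster id is the feature value.
  Default k = 400 with a 100–1000 grid, matching the scale used for
  MEDLINE-sized vocabularies; synthetic fixtures pass small k explicitly.
  Out-of-vocabulary words share the dedicated id `OOV`, keeping extraction
  total and deterministic.

Conjunction features join two singleton values with `_`; member values are
escaped (`_` → `\_`, `\` → `\\`) so serialization stays injective.  A
conjunction with a missing member (an omitted short-word affix, a template
without its resource) is suppressed entirely — a half-empty conjunction
encodes nothing its surviving member doesn't.  Only 2-tuples are shipped;
the template machinery is arity-general but larger tuples explode the
feature space.  The noisy shape-bigram set (f15 window bigrams) can be
built via the custom template-set config for experimentation; no behavior
claim is attached to it.

## Feature selection

Selection statistics are computed on **training tokens only**.  The event
unit is the token: each token contributes one (feature-set, tag) event.
The class variable is the coarse tag {B, I, L, O, U} — position letters
pooled across entity types after collapsing each typed tag (a
`typed_selection` flag scores against the full 17-tag space instead).
Conventions: 0·log 0 := 0 throughout; a 2×2 table with a zero marginal
scores 0 (the statistic is undefined and the feature or tag carries no
contrast); floating-point-negative information gains are clipped to 0.

Top-fraction selection converts p to a count by round-half-away-from-zero
(294 782 features at p = 0.4 → 117 913) and breaks score ties by the
serialized feature string, ascending.  Stable ordering makes the retained
subsets nested across fractions.

## Evaluation

Matching is one-to-one under four criteria: strict (boundary + type),
exact (boundary), type (≥ 1 character overlap, same type), partial
(≥ 1 character overlap).  The default assignment is greedy — gold mentions
in document order, each taking the first unconsumed qualifying prediction
in start order; an exhaustive maximum assignment (Kuhn's augmenting-path
algorithm) ships alongside as the oracle, and the two agree on all small
random fixtures exercised in the tests.  With non-overlapping gold
mentions the greedy TP counts preserve the criterion ordering
strict ≤ exact ≤ partial and strict ≤ type ≤ partial.  Scores are
micro-averaged percentages; zero denominators score 0.

## Synthetic data

The generator emulates what a DDI-style corpus offers a tagger, not its
prose: template sentences with 1–3-token mention slots, a type mixture
defaulting to {drug 0.64, group 0.23, brand 0.09, no-human 0.04} (the
drug-dominant, no-human-rare skew of real corpora), drug names as
lowercase coinages with pharmacological suffixes (-mab, -vir, -cillin, …),
brands as capitalized coinages, groups as plural class nouns, no-human
agents with agrochemical-style morphology, plus alphanumeric names
(`interleukin-2`) and salt-suffixed combinations.  Ambiguous terms appear
both as mentions and as plain modifiers at a configurable rate, so context
and conjunction features carry value beyond the lexicon.  Dictionaries
cover a seeded exact fraction (default 0.8) of the distinct drug words
plus common-word distractors, with three lexicons of different breadth;
embeddings are sampled from well-separated per-type Gaussian centers
(dimension 50 by default, center sd 5, within-group sd 0.5) with a 10 %
OOV exclusion.  One global seed fans out to per-component streams through
`numpy.random.SeedSequence`.

What passing on this corpus shows: the pipeline is wired correctly — the
codec round-trips, features fire where constructed, selection ranks
planted signal above noise, the CRF recovers strongly-cued entities.  What
it does not show: performance on real biomedical text, whose morphology is
weaker, whose dictionaries are noisier, and whose POS/chunk signal needs a
real tagger.  Near-perfect synthetic F1 is the healthy-pipeline reading,
nothing more.

## Problem sizes and numerics

The end-to-end experiment in the tests and the acceptance script uses 300
training / 100 test sentences with the full singleton + S1 + S2 feature
set (~10 k instantiated features), chosen as the smallest scale at which
every feature family is exercised with a comfortable margin over the
recovery bar.  CRF fits cap L-BFGS at 150–200 iterations with ftol 1e-6;
the tiny-corpus tests use lower caps.  Convergence status is carried on
the results object.  Model persistence uses one `.npz` (weights + label
and vocabulary metadata) plus a JSON sidecar naming the retained feature
set.

## Known limitations

* Overlapping, nested, or discontinuous mentions are out of scope by
  construction of the one-tag-per-token formulation.
* The bundled POS/chunk tagger is intentionally simple; its labels are
  only as informative as its suffix rules.
* MI and IG use raw plug-in estimates; no smoothing, so very rare features
  get noisy scores (selection mitigates this only by ranking).
* The CRF stores a dense (features × labels) weight matrix; at
  MEDLINE-scale vocabularies memory, not time, becomes the binding
  constraint.
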