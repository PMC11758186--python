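# Methods

## Scope and design

The package reproduces, as a reusable pipeline, the common study design
for emotion and theme analysis of short Chinese social-media text:
lexicon-based seven-category emotion classification with intensity
weighting, LDA topic modeling with perplexity/coherence model selection,
and dual-annotator validation statistics. Because microblog corpora
cannot be redistributed, the package's empirical claims are made against
synthetic corpora with planted ground truth; what that does and does not
establish is discussed at the end.

## Preprocessing

Cleaning removes HTML tags (non-greedy `<...>` pattern), URLs
(scheme/host pattern, terminated by whitespace or a CJK character), and
then every character that is not a Unicode letter or digit. This is a
closed operationalization of "remove URLs, punctuation and special
characters": CJK ideographs are Unicode letters and survive. Cleaning is
idempotent, and characters are counted in code points.

The validity filter drops posts with fewer than 10 cleaned characters.
Applying it to the *cleaned* text is a deliberate choice (configurable via
`on_cleaned`): a URL alone can exceed 10 raw characters while carrying no
analyzable content.

Segmentation is forward maximum matching (FMM) over the lexicon
vocabulary plus an optional user dictionary: at each position, the
longest dictionary word starting there is emitted, otherwise one
character. FMM is deterministic, lossless (the concatenation of tokens
reproduces the input, a property-tested invariant), and sufficient for
dictionary-based emotion matching, which only requires locating lexicon
words. Any external segmenter can be plugged in through the `tokenizer`
callable of `preprocess_corpus`.

## Emotion classification

The affect lexicon follows the DUTIR structure: word → (POS class, one of
7 categories, optional subcategory, intensity ∈ {1,3,5,7,9}, polarity
∈ {0,1,2,3}), with an optional auxiliary (category, intensity, polarity)
attribution per word. Polarity and subcategory are stored and reported
but play no role in scoring — classification is by emotion category
distribution only.

Each matched token occurrence contributes its attribution(s) to the
document's category counts and scores. Decisions left open by the study
design are exposed as flags with documented defaults:

* **Weighting** (`intensity` default, `count` available): the reporting
  convention records intensity for every keyword, so the default dominant
  score is the intensity-weighted sum; the count mode exists for
  sensitivity analysis. Both agree whenever all matched words share one
  intensity level (tested).
* **Auxiliary attributions** (`use_aux=True` default): a word's second
  emotion is counted alongside its primary one; at most two attributions
  per token.
* **Tie-break**: exact score ties resolve by the fixed category order
  Good, Happy, Anger, Disgust, Sadness, Surprise, Fear.
* **Neutral documents** (no matched words) are excluded from the
  proportion denominator by default so the seven shares sum to 1, with
  the neutral count reported separately; `include_neutral=True` adds an
  eighth `none` share.

Per-category keyword tables rank a category's lexicon words by total
occurrence frequency (primary category only; ties lexicographic) and
attach POS class and intensity.

## Topic model

LDA is fitted by collapsed Gibbs sampling — the model and the selection
metrics are what matter here, and both are estimator-agnostic, so the
compact exact-in-the-limit sampler is preferred over a variational
implementation. The inner loop is numba-compiled; the sampler's RNG is
seeded per fit, making every model a pure function of (corpus, config,
seed).

Defaults: α = 50/K, β = 0.01, 1,000 sweeps with 200 burn-in (the analysis
scripts use 500/200 at their corpus sizes, which the recovery tests show
is ample). φ and θ are posterior means computed from the post-burn-in
average counts; for K = 1 this collapses to the β-smoothed corpus unigram
distribution exactly (tested to 1e-12).

Perplexity is exp(−Σ_d log p(w_d) / Σ_d N_d) with
log p(w_d) = Σ_i log Σ_k θ_dk φ_k,w_i, evaluated on the training corpus
by default (no held-out split is prescribed in this study design); a
fold-in mode (`infer_theta`) supports held-out evaluation. The log of
perplexity is always reported alongside: toolkits differ in sign
convention for "log perplexity" (some report the per-word log-likelihood
bound, the negative of ours), which is why published absolute values of
these scores are not comparable across implementations — both quantities
here are defined exactly as above and verified against an independent
brute-force token-by-token oracle.

Coherence is UMass: mean over topics of Σ_{j<i} log[(D(w_i,w_j)+1)/D(w_j)]
over each topic's top-10 words, with D() the document-frequency counts of
the scored corpus. UMass is chosen because it is fully determined by the
corpus — no external reference corpus, sliding window, or embedding
choices — hence reproducible to the digit.

**Selecting K.** Among interior local maxima of the coherence-vs-K curve,
the implementation picks the K with the *highest coherence*; exact
coherence ties break by lower perplexity, remaining ties by smaller K;
with no interior peak, the global coherence maximum. The coherence peak
is the selection signal: training perplexity decreases essentially
monotonically in K, so any rule that ranks candidate peaks by perplexity
degenerates into picking the largest-K wiggle of the coherence curve.
On planted-topic corpora the coherence peak at the true K is large
(≈ −29 vs ≈ −33..−55 at neighboring K in the worked example) while
off-peak wiggles are ~1–3 units, so the rule recovers the planted K
reliably (stochastic test: ≥ 8/10 seeds).

Topic intensity is the mean document-topic weight, intensity_k =
(1/M) Σ_d θ_dk, which sums to 1 across topics; a token-assignment-share
mode is available as a flag.

## Validation statistics

Cohen's kappa is computed from the confusion matrix as (po − pe)/(1 − pe)
and banded 0.61–0.80 good, 0.81–1 excellent (finer subdivisions below
0.61 are not distinguished). The degenerate case pe = 1 (both raters
constant and identical) is reported as such with po = 1 rather than a
number. Multi-class precision/recall/F1 use one-vs-rest counts; macro
(unweighted class mean) is the default headline averaging — the stricter,
class-balanced convention — with micro one flag away (for single-label
data micro P = R = F1 = accuracy, asserted in tests). The validity gate
passes a metric iff it is ≥ its threshold (defaults 0.85/0.80/0.80).
Topic→theme mapping agreement treats topics as items and themes as
labels and reuses kappa. The implementation is cross-checked against
scikit-learn's metrics to 1e-12 on random fixtures.

## Synthetic-data generator

The generator emulates the structure of a policy-discourse microblog
corpus at desk scale; defaults are the package's study conditions:

* **Emotion mix** (planted dominant-category shares): Good 0.46,
  Happy 0.11, Anger 0.17, Disgust 0.06, Sadness 0.10, Surprise 0.02,
  Fear 0.08 — the Good-dominant profile typical of opening-up-policy
  discourse. At 5,000 docs the realized shares match the mix within 0.02
  (tested).
* **Documents**: 8–30 background tokens drawn from K_true = 3 planted
  topic-word rows over a 300-word neutral vocabulary, θ ~ Dirichlet(0.1)
  (documents mostly near one topic, as short posts are). Planted rows are
  Dirichlet(0.1) over each topic's block — a skewed, Zipf-like profile in
  which many vocabulary words are rare, as in natural text. The
  `vocab_overlap` knob moves a shared block between all topics
  (0 = disjoint supports).
* **Emotion injection**: with probability 1 − neutral_rate (default
  0.05), a planted category is drawn from the mix and 2–4 emotion-word
  slots are injected. Each slot flips to a uniformly random other
  category with probability `contamination` (default 0.1). With zero
  contamination the planted category is the strict intensity-score winner
  by construction (only injected words carry emotion), so ground truth is
  decision-rule-independent; with contamination ε the truth label stays
  the planted category and classifier accuracy may drop, bounded near
  1 − ε since a flip requires the off-category intensity sum to beat the
  planted one.
* **Words** are unique fixed-length (2-character) CJK strings with
  disjoint index ranges for thematic vocabulary, emotion words, and stop
  words; because every planted token is in the segmentation dictionary,
  FMM re-segments the concatenated text into exactly the planted tokens.
  Punctuation ("!!") and URL suffixes are sprinkled onto the raw text to
  exercise cleaning.
* **Timestamps** follow a configurable per-day expected-volume profile
  over Dec 2022 – Jan 2023, default flat with an early announcement spike
  (5×) and a later travel-rush spike (3×) — a qualitative emulation of
  event-driven posting peaks, not of any real daily counts.
* **Annotators**: two independent raters copy the truth label and err
  with probability `annotator_error` (default 0.05, which yields kappa
  ≈ 0.87 on the seven-category task — the "excellent" band).

What the generator does *not* emulate: natural language (no syntax,
negation, sarcasm, or degree adverbs), retweet/user-network structure,
duplicate posts, emoji, or topic-emotion correlation (emotions are
injected independently of the document's topic mixture). Passing tests
therefore demonstrate that the pipeline's computations are correct and
its estimators recover planted structure — not that lexicon matching is
semantically adequate for real discourse, which is exactly what the
dual-annotator validation protocol is for on real data.

## Numerical and engineering choices

* Problem sizes in tests and analysis scripts (5,000-post emotion corpus;
  500-doc, 500-sweep topic corpora; K sweeps over 1..8) are chosen so the
  planted-recovery margins are comfortable at interactive runtimes.
* Stochastic tests fix seeds; determinism contracts are tested as
  bit-identity (same seed ⇒ identical z, φ, θ; same run config ⇒
  hash-identical pipeline outputs, with no wall-clock values in outputs).
* The K sweep re-seeds each fit with seed + K: fits are independent but
  the whole sweep is reproducible.
* Degenerate inputs: an all-neutral corpus yields a flagged all-zero
  proportion summary; an empty bag-of-words skips topic modeling with a
  manifest warning; a failing pipeline stage writes a `FAILED` marker
  naming the stage and keeps partial outputs.
* Coherence pairs whose conditioning word never occurs in the scored
  corpus are excluded with a warning (cannot happen when the model was
  fitted on that corpus).

## Known limitations

* FMM segmentation has no out-of-vocabulary word discovery; real corpora
  should supply a user dictionary or an external segmenter backend.
* Lexicon matching ignores negation and degree modifiers; scores are
  additive in matched words.
* Training-corpus perplexity is not a generalization estimate; use the
  fold-in mode with a held-out split for that.
* The Gibbs sampler is single-chain; label switching across seeds is
  expected and handled in evaluation by greedy topic matching.
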