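# emotopic

Emotion and topic mining for short Chinese social-media text, built for
infodemiology-style studies of public discourse around health-policy
events (the motivating case: microblog posts about COVID-19 opening-up
policies).

The package implements a complete, deterministic, testable version of the
standard study design in this area:

1. **Preprocessing** — strip URLs, HTML tags, punctuation and symbols;
   drop posts whose cleaned text is shorter than 10 characters; segment by
   deterministic forward maximum matching against the affect lexicon plus
   a user dictionary; remove stop words.
2. **Lexicon-based emotion classification** — a DUTIR-style affect
   dictionary maps each word to one of seven categories (Good, Happy,
   Anger, Disgust, Sadness, Surprise, Fear) with an intensity level in
   {1, 3, 5, 7, 9} and a polarity code. A document's score for category
   *c* is the intensity-weighted sum over matched words,
   s_c = Σ_{w matched, cat(w)=c} intensity(w), and its dominant emotion is
   argmax_c s_c. Corpus-level proportions, per-category top-10 keyword
   tables, and daily post-count series reproduce the usual reporting.
3. **Topic modeling** — latent Dirichlet allocation fitted by collapsed
   Gibbs sampling: P(z_i = k | z_−i, w) ∝ (n_dk + α)(n_kw_i + β)/(n_k + Vβ),
   with posterior-mean estimates φ_kw = (n_kw + β)/(n_k + Vβ) and
   θ_dk = (n_dk + α)/(N_d + Kα). Models across K are scored by corpus
   perplexity, exp(−Σ_d log p(w_d)/Σ_d N_d), and UMass coherence; the
   operating K is the coherence peak. Topic keyword tables and
   topic-intensity shares (mean θ) summarize the selected model.
4. **Validation statistics** — Cohen's kappa with the 0.61–0.80 good /
   0.81–1 excellent banding, multi-class precision/recall/F1 (macro and
   micro), the excellent-validity gate (accuracy ≥ 0.85, recall ≥ 0.80,
   F1 ≥ 0.80), and agreement between two topic→theme mappings.
5. **Synthetic corpora** — real microblog corpora cannot be
   redistributed, so a generator plants every quantity the pipeline is
   supposed to estimate: a dominant-emotion mix, latent topic-word
   distributions, daily-volume profiles with spike days, and simulated
   dual annotators. All outputs are pure functions of (config, seed).

## Worked example

The `analysis/` scripts run the full study design on a 5,000-post
synthetic corpus (planted mix: Good 46%, Happy 11%, Anger 17%, Disgust 6%,
Sadness 10%, Surprise 2%, Fear 8%; 10% contamination; 5% neutral posts;
3 latent topics over 300 thematic words):

```sh
python analysis/01_simulate_corpus.py
python analysis/02_emotion_analysis.py
python analysis/03_topic_model.py
python analysis/04_validation.py
```

`02_emotion_analysis.py` prints the recovered proportions —

```
4771 classified, 229 neutral
emotion proportions (share of classified posts):
  Good      45.5%
  Happy     11.5%
  Anger     15.5%
  ...
```

— close to, but not exactly, the planted mix: 10% of injected emotion-word
slots are off-category, so a small fraction of posts is legitimately
misclassified. `03_topic_model.py` sweeps K = 1..8 and shows the
selection signal —

```
  K=2: perplexity   45.22  coherence  -55.20
  K=3: perplexity   36.15  coherence  -29.24 <-- selected
  K=4: perplexity   36.66  coherence  -32.58
topic intensity: 33.4%, 33.3%, 33.3%
matched cosine to planted topics: 1.000, 1.000, 1.000
```

— coherence peaks sharply at the planted K = 3 while perplexity keeps
drifting down with K, and the fitted topic-word rows match the planted
ones with cosine 1.000. `04_validation.py` reports annotator kappa 0.870
(excellent band) and a classifier validity of accuracy 0.952 / macro
recall 0.944 / macro F1 0.916 against the planted gold labels, passing
the excellent-validity gate.

The same stages are available as a CLI (`emotopic simulate|clean|classify|
topics|select-k|evaluate|report|run-all`); `run-all` executes the whole
pipeline from a YAML config into a run directory with a manifest that
makes reruns bit-for-bit reproducible.

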