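#!/usr/bin/env python
"""Fit LDA over a range of topic numbers and summarize the selected model.

Reads results/data/ (run 01_simulate_corpus.py first), builds the
bag-of-words corpus from the preprocessed tokens, sweeps K = 1..8 with
500-sweep collapsed Gibbs fits, scores each by perplexity and UMass
coherence, applies the peak-coherence selection rule, and reports the
selected model's keyword and intensity tables together with the recovery
of the planted topics.

Writes ksweep.csv, topic_keywords.csv and topic_intensity.csv under
results/topics/.
"""

import csv
from pathlib import Path

from emotopic.lexicon import load_lexicon, load_stopwords
from emotopic.preprocess import preprocess_corpus, read_corpus_jsonl
from emotopic.synthetic_data import GeneratorConfig, generate_corpus, planted_phi_on_vocab
from emotopic.topic_model import (BowCorpus, fit_lda, greedy_topic_match,
                                  summarize_topics, sweep_k)

DATA = Path("results/data")
OUT = Path("results/topics")
SEED = 20221207 % (2 ** 30)


def main() -> None:
    posts = read_corpus_jsonl(DATA / "corpus.jsonl")
    lexicon = load_lexicon(DATA / "lexicon.tsv")
    stopwords = load_stopwords(DATA / "stopwords.txt")
    user_dict = load_stopwords(DATA / "userdict.txt")
    docs, _ = preprocess_corpus(posts, lexicon, stopwords=stopwords,
                                user_dict=user_dict | stopwords)
    # topics live in the thematic vocabulary; emotion words are a separate
    # channel, so restrict the bag-of-words to the planted neutral vocabulary
    bow = BowCorpus.from_tokenized(
        [[t for t in d.tokens if t in user_dict] for d in docs])
    print(f"bag-of-words: {bow.M} docs, V={bow.V}, {bow.n_tokens} tokens")

    sweep = sweep_k(bow, range(1, 9), iterations=500, burn_in=200, seed=SEED)
    for r in sweep.records:
        marker = " <-- selected" if r.K == sweep.selected_K else ""
        print(f"  K={r.K}: perplexity {r.perplexity:7.2f}  "
              f"coherence {r.coherence:7.2f}{marker}")

    OUT.mkdir(parents=True, exist_ok=True)
    with (OUT / "ksweep.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["K", "perplexity", "log_perplexity", "coherence"],
            lineterminator="\n")
        writer.writeheader()
        writer.writerows(sweep.to_rows())

    model = fit_lda(bow, sweep.selected_K, iterations=500, burn_in=200,
                    seed=SEED + sweep.selected_K)
    summary = summarize_topics(model, bow, topN=10)
    with (OUT / "topic_keywords.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["topic", "rank", "keyword", "probability"])
        for k, pairs in enumerate(summary.topics):
            for rank, (word, prob) in enumerate(pairs, 1):
                writer.writerow([k, rank, word, f"{prob:.6g}"])
    with (OUT / "topic_intensity.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["topic", "intensity"])
        for k, v in enumerate(summary.intensity):
            writer.writerow([k, f"{v:.6g}"])
    print("topic intensity:",
          ", ".join(f"{100 * v:.1f}%" for v in summary.intensity))

    # recovery against the planted topics (regenerate the truth)
    truth_corpus = generate_corpus(GeneratorConfig(seed=SEED, n_docs=5000))
    ref = planted_phi_on_vocab(truth_corpus, bow.vocabulary)
    if model.K >= ref.shape[0]:
        pairs = greedy_topic_match(model.phi, ref)
        print("matched cosine to planted topics:",
              ", ".join(f"{c:.3f}" for _, _, c in pairs))
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
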