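#!/usr/bin/env python
"""Classify the corpus into the seven emotion categories and summarize.

Reads results/data/ (run 01_simulate_corpus.py first), applies cleaning,
the 10-character validity filter, dictionary segmentation and stop-word
removal, matches tokens against the affect lexicon with intensity
weighting, and reports the corpus emotion proportions and the top-10
keyword table per category.

Writes summary.json and keywords/<category>.csv under results/emotions/.
"""

import csv
import json
from pathlib import Path

from emotopic.lexicon import EMOTIONS, load_lexicon, load_stopwords
from emotopic.preprocess import preprocess_corpus, read_corpus_jsonl
from emotopic.sentiment import classify_corpus, corpus_proportions, keyword_tables

DATA = Path("results/data")
OUT = Path("results/emotions")


def main() -> None:
    posts = read_corpus_jsonl(DATA / "corpus.jsonl")
    lexicon = load_lexicon(DATA / "lexicon.tsv")
    stopwords = load_stopwords(DATA / "stopwords.txt")
    user_dict = load_stopwords(DATA / "userdict.txt")

    docs, dropped = preprocess_corpus(posts, lexicon, stopwords=stopwords,
                                      user_dict=user_dict | stopwords)
    print(f"{len(posts)} posts, {dropped} dropped by the <10-character filter")

    profiles = classify_corpus(docs, lexicon)
    summary = corpus_proportions(profiles)
    print(f"{summary.n_classified} classified, {summary.n_neutral} neutral")
    print("emotion proportions (share of classified posts):")
    for e in EMOTIONS:
        print(f"  {e:<9}{100 * summary.proportions[e]:5.1f}%")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "summary.json").write_text(json.dumps(
        {"proportions": summary.proportions,
         "n_classified": summary.n_classified,
         "n_neutral": summary.n_neutral}, indent=1, sort_keys=True),
        encoding="utf-8")

    (OUT / "keywords").mkdir(exist_ok=True)
    for emotion, stats in keyword_tables(docs, lexicon, k=10).items():
        with (OUT / "keywords" / f"{emotion}.csv").open(
                "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["word", "frequency", "pos_class", "intensity"])
            for s in stats:
                writer.writerow([s.word, s.frequency, s.pos_class, s.intensity])
    top_good = keyword_tables(docs, lexicon, k=3)["Good"]
    print("top Good keywords:",
          ", ".join(f"{s.word}({s.frequency})" for s in top_good))
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
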