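#!/usr/bin/env python
"""Validation statistics: annotator agreement and classifier validity.

Reads results/data/ (run 01_simulate_corpus.py first; 02 for the
classifier outputs is re-run here in memory), simulates the
dual-annotator protocol over the planted labels, computes Cohen's kappa
with the good/excellent banding, scores the lexicon classifier against
the planted gold labels (accuracy, macro recall, macro F1) and applies
the excellent-validity gate (accuracy >= 0.85, recall >= 0.80,
F1 >= 0.80).  Also demonstrates topic-to-theme mapping agreement.

Writes agreement.json and validity.json under results/validation/.
"""

import json
from pathlib import Path

from emotopic.evaluation import (LabelVectorPair, cohen_kappa,
                                 prf_multiclass, theme_mapping_agreement,
                                 validity_gate)
from emotopic.lexicon import load_lexicon, load_stopwords
from emotopic.preprocess import preprocess_corpus, read_corpus_jsonl
from emotopic.sentiment import classify_corpus
from emotopic.synthetic_data import generate_annotations

DATA = Path("results/data")
OUT = Path("results/validation")
SEED = 20221207 % (2 ** 30)


def main() -> None:
    truth = json.loads((DATA / "truth.json").read_text(encoding="utf-8"))["truth"]
    posts = read_corpus_jsonl(DATA / "corpus.jsonl")
    lexicon = load_lexicon(DATA / "lexicon.tsv")
    stopwords = load_stopwords(DATA / "stopwords.txt")
    user_dict = load_stopwords(DATA / "userdict.txt")

    # dual simulated annotators over the emotional posts
    labels = [truth[p.post_id]["emotion"] for p in posts
              if truth[p.post_id]["emotion"] is not None]
    ann_a, ann_b = generate_annotations(labels, annotator_error=0.05,
                                        seed=SEED + 1)
    agreement = cohen_kappa(LabelVectorPair.from_sequences(ann_a, ann_b))
    print(f"annotator kappa {agreement.kappa:.3f} ({agreement.band}); "
          f"po={agreement.po:.3f}, pe={agreement.pe:.3f}")

    # classifier vs planted gold labels
    docs, _ = preprocess_corpus(posts, lexicon, stopwords=stopwords,
                                user_dict=user_dict | stopwords)
    pred = {p.post_id: p.dominant for p in classify_corpus(docs, lexicon)}
    ids = [p.post_id for p in posts
           if truth[p.post_id]["emotion"] is not None
           and pred.get(p.post_id) is not None]
    pair = LabelVectorPair.from_sequences(
        [truth[i]["emotion"] for i in ids], [pred[i] for i in ids], ids=ids)
    report = prf_multiclass(pair, averaging="macro")
    gates = validity_gate(report)
    print(f"classifier vs gold (n={len(ids)}): accuracy {report.accuracy:.3f}, "
          f"macro recall {report.recall:.3f}, macro F1 {report.f1:.3f}")
    print("validity gate:", ", ".join(f"{k}={'pass' if v else 'FAIL'}"
                                      for k, v in gates.items()))

    # topic->theme mapping agreement (two hypothetical coders, 8 topics, 3 themes)
    map_a = {f"t{i}": ("policy", "medical", "daily_life")[i % 3] for i in range(8)}
    map_b = dict(map_a)
    map_b["t7"] = "policy"
    themes = theme_mapping_agreement(map_a, map_b)
    print(f"theme-mapping kappa (1 of 8 topics disputed): {themes.kappa:.3f}")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "agreement.json").write_text(json.dumps(
        {"kappa": agreement.kappa, "band": agreement.band,
         "po": agreement.po, "pe": agreement.pe, "n": len(labels)},
        indent=1, sort_keys=True), encoding="utf-8")
    (OUT / "validity.json").write_text(json.dumps(
        {"accuracy": report.accuracy, "recall": report.recall,
         "f1": report.f1, "gates": gates, "n": len(ids)},
        indent=1, sort_keys=True), encoding="utf-8")
    print(f"reports written under {OUT}")


if __name__ == "__main__":
    main()
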