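"""Lexicon matching, per-document emotion profiles, corpus aggregation,
and per-emotion keyword tables.

Each token occurrence is matched against the lexicon; matched words
contribute their attribution(s) to the document's per-category counts and
scores.  Scores are intensity-weighted sums by default (``weighting=
"intensity"``), or plain match counts (``weighting="count"``).  The
document's dominant emotion is the argmax of the scores; exact ties break
by the canonical category order (Good, Happy, Anger, Disgust, Sadness,
Surprise, Fear).  Documents with no matched words are neutral
(``dominant is None``) and excluded from corpus proportions by default, so
the seven reported shares sum to 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .lexicon import EMOTIONS, EmotionLexicon
from .preprocess import TokenizedDoc

_EMOTION_RANK = {e: i for i, e in enumerate(EMOTIONS)}


@dataclass(frozen=True)
class EmotionProfile:
    post_id: str
    scores: dict[str, float]   # emotion -> intensity-weighted (or count) score
    counts: dict[str, int]     # emotion -> number of matched attributions
    dominant: str | None       # None iff no matches at all

    def as_record(self) -> dict:
        return {"post_id": self.post_id, "counts": dict(self.counts),
                "scores": dict(self.scores), "dominant": self.dominant}


@dataclass(frozen=True)
class CorpusEmotionSummary:
    proportions: dict[str, float]
    n_classified: int
    n_neutral: int
    degenerate: bool = False   # True when no document could be classified


@dataclass(frozen=True)
class KeywordStat:
    word: str
    frequency: int
    pos_class: str
    intensity: int


def match_emotions(
    doc: TokenizedDoc,
    lexicon: EmotionLexicon,
    use_aux: bool = True,
    weighting: str = "intensity",
) -> EmotionProfile:
    """Compute the emotion profile of one tokenized document.

    Every token occurrence contributes independently (repeated words count
    each time).  With ``use_aux=True`` a word's auxiliary attribution is
    counted alongside its primary one.
    """
    if weighting not in ("intensity", "count"):
        raise ValueError(f"weighting must be 'intensity' or 'count', got {weighting!r}")
    counts = {e: 0 for e in EMOTIONS}
    scores = {e: 0.0 for e in EMOTIONS}
    for tok in doc.tokens:
        attrs = lexicon.lookup(tok)
        if not use_aux:
            attrs = attrs[:1]
        for a in attrs:
            counts[a.emotion] += 1
            scores[a.emotion] += a.intensity if weighting == "intensity" else 1.0
    if sum(counts.values()) == 0:
        dominant = None
    else:
        dominant = max(EMOTIONS, key=lambda e: (scores[e], -_EMOTION_RANK[e]))
    return EmotionProfile(post_id=doc.post_id, scores=scores, counts=counts,
                          dominant=dominant)


def classify_corpus(
    docs: Sequence[TokenizedDoc],
    lexicon: EmotionLexicon,
    use_aux: bool = True,
    weighting: str = "intensity",
) -> list[EmotionProfile]:
    """One profile per document, input order preserved; deterministic."""
    return [match_emotions(d, lexicon, use_aux=use_aux, weighting=weighting)
            for d in docs]


def corpus_proportions(
    profiles: Sequence[EmotionProfile], include_neutral: bool = False,
) -> CorpusEmotionSummary:
    """Corpus-level dominant-emotion shares.

    With ``include_neutral=False`` the denominator is the classified
    documents only (the seven shares sum to 1) and the neutral count is
    reported separately; with ``include_neutral=True`` an eighth ``none``
    share appears and the denominator is all documents.
    """
    dominants = Counter(p.dominant for p in profiles)
    n_neutral = dominants.pop(None, 0)
    n_classified = sum(dominants.values())
    categories = EMOTIONS + (("none",) if include_neutral else ())
    denom = n_classified + (n_neutral if include_neutral else 0)
    if denom == 0:
        return CorpusEmotionSummary(
            proportions={c: 0.0 for c in categories},
            n_classified=0, n_neutral=n_neutral, degenerate=True)
    props = {e: dominants.get(e, 0) / denom for e in EMOTIONS}
    if include_neutral:
        props["none"] = n_neutral / denom
    return CorpusEmotionSummary(proportions=props, n_classified=n_classified,
                                n_neutral=n_neutral)


def top_keywords(
    docs: Sequence[TokenizedDoc],
    lexicon: EmotionLexicon,
    emotion: str,
    k: int = 10,
) -> list[KeywordStat]:
    """The ``k`` highest-frequency lexicon words of one category.

    Frequency is the total occurrence count across all documents; a word is
    attributed to the category of its primary lexicon record.  Ties break
    lexicographically.  Returns fewer than ``k`` entries when fewer words of
    the category occur; never pads.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion category {emotion!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    freq: Counter[str] = Counter()
    for d in docs:
        for tok in d.tokens:
            entry = lexicon.entries.get(tok)
            if entry is not None and entry.emotion == emotion:
                freq[tok] += 1
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return [
        KeywordStat(word=w, frequency=n,
                    pos_class=lexicon.entries[w].pos_class,
                    intensity=lexicon.entries[w].intensity)
        for w, n in ranked
    ]


def keyword_tables(
    docs: Sequence[TokenizedDoc], lexicon: EmotionLexicon, k: int = 10,
) -> dict[str, list[KeywordStat]]:
    """Top-``k`` keyword table for every category."""
    return {e: top_keywords(docs, lexicon, e, k=k) for e in EMOTIONS}
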