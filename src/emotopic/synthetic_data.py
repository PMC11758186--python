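"""Synthetic microblog corpora with known ground truth.

Real microblog corpora cannot be redistributed, so every pipeline stage is
exercised against generated data whose emotional and thematic structure is
planted and therefore exactly known:

* a synthetic affect lexicon in the same tabular dialect as the real
  resource (7 categories, intensities in {1,3,5,7,9}, valence-consistent
  polarities, all 7 POS classes);
* short documents drawn from a latent-topic mixture (θ_d ~ Dirichlet(α),
  words from planted topic-word rows φ_true over a neutral vocabulary with
  controlled cross-topic overlap);
* category-tagged emotion words injected per document so the planted
  dominant category is the strict intensity-score winner; an optional
  contamination rate swaps injected slots to off-category words (the truth
  label stays the planted category, so classifier accuracy may drop
  toward 1 − contamination);
* timestamps following a configurable daily-volume profile with spike days
  (emulating announcement / travel-rush peaks qualitatively);
* a pair of simulated annotators who copy the truth label and independently
  err with a configurable probability.

Words are fixed-length (2-character) unique CJK strings, so the
forward-maximum-matching tokenizer re-segments the concatenated text into
exactly the planted tokens.  Every output is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .lexicon import (EMOTIONS, POS_CLASSES, Attribution, EmotionLexicon,
                      LexiconEntry, write_lexicon, write_stopwords)
from .preprocess import RawPost, write_corpus_jsonl

#: Default planted dominant-emotion mix: the seven-category share profile
#: reported for opening-up-policy discourse (Good-dominant, Anger second).
DEFAULT_EMOTION_MIX: dict[str, float] = {
    "Good": 0.46, "Happy": 0.11, "Anger": 0.17, "Disgust": 0.06,
    "Sadness": 0.10, "Surprise": 0.02, "Fear": 0.08,
}

#: Intensity level frequencies, mid-heavy like a typical affect dictionary.
DEFAULT_INTENSITY_DIST: dict[int, float] = {1: 0.10, 3: 0.25, 5: 0.35, 7: 0.20, 9: 0.10}

_POLARITY_OF = {"Good": 1, "Happy": 1, "Anger": 2, "Sadness": 2,
                "Fear": 2, "Disgust": 2, "Surprise": 3}

_CHAR_POOL = [chr(0x4E00 + i) for i in range(256)]


def _word(index: int) -> str:
    """Unique fixed-length (2-char) CJK word for a global word index."""
    return _CHAR_POOL[index // 256] + _CHAR_POOL[index % 256]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 1000
    doc_length: tuple[int, int] = (8, 30)        # background tokens per doc
    K_true: int = 3
    V: int = 300                                  # neutral vocabulary size
    topic_alpha: float = 0.1                      # document-topic Dirichlet
    topic_beta: float = 0.1                       # planted topic-word Dirichlet
    vocab_overlap: float = 0.0                    # share of V common to all topics
    emotion_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_MIX))
    contamination: float = 0.1                    # off-category injected-slot rate
    neutral_rate: float = 0.05                    # docs with no emotion words
    intensity_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_DIST))
    words_per_category: int = 10
    emo_words_per_doc: tuple[int, int] = (2, 4)
    n_stopwords: int = 20
    stopword_rate: float = 0.05                   # stop-word tokens per background token
    punct_noise_rate: float = 0.3                 # raw-text punctuation noise
    url_noise_rate: float = 0.05                  # raw-text URL noise
    date_range: tuple[str, str] = ("2022-12-01", "2023-01-31")
    daily_profile: tuple[float, ...] | None = None  # per-day relative volumes
    annotator_error: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.emotion_mix.values()) - 1.0) > 1e-9:
            raise ValueError("emotion_mix must sum to 1")
        if set(self.emotion_mix) - set(EMOTIONS):
            raise ValueError("emotion_mix contains unknown categories")
        for name in ("vocab_overlap", "contamination", "neutral_rate",
                     "stopword_rate", "annotator_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.doc_length[0] > self.doc_length[1] or self.doc_length[0] < 1:
            raise ValueError("doc_length must satisfy 1 <= min <= max")
        if self.K_true < 1 or self.V < self.K_true:
            raise ValueError("need V >= K_true >= 1")

    def days(self) -> list[date]:
        start = date.fromisoformat(self.date_range[0])
        end = date.fromisoformat(self.date_range[1])
        return [start + timedelta(days=i) for i in range((end - start).days + 1)]

    def day_weights(self) -> np.ndarray:
        """Relative expected daily volumes; default is a flat baseline with
        an early announcement spike and a later travel-rush spike."""
        n = len(self.days())
        if self.daily_profile is not None:
            w = np.asarray(self.daily_profile, dtype=float)
            if len(w) != n:
                raise ValueError("daily_profile length must match date_range days")
        else:
            w = np.ones(n)
            if n > 8:
                w[6] = 5.0
            if n > 46:
                w[45] = 3.0
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("daily_profile must be non-negative and non-trivial")
        return w / w.sum()


@dataclass
class SyntheticCorpus:
    posts: list[RawPost]
    truth: dict[str, dict]              # post_id -> {emotion, theta}
    lexicon: EmotionLexicon
    phi_true: np.ndarray                # K_true x V planted topic-word rows
    stopwords: frozenset[str]
    neutral_vocab: list[str]
    config: GeneratorConfig

    @property
    def truth_labels(self) -> list[str | None]:
        return [self.truth[p.post_id]["emotion"] for p in self.posts]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus_jsonl(self.posts, out / "corpus.jsonl")
        write_lexicon(self.lexicon, out / "lexicon.tsv")
        write_stopwords(self.stopwords, out / "stopwords.txt")
        payload = {
            "truth": self.truth,
            "phi_true": self.phi_true.tolist(),
            "neutral_vocab": self.neutral_vocab,
            "config": asdict(self.config),
        }
        (out / "truth.json").write_text(
            json.dumps(payload, ensure_ascii=False, sort_keys=True, indent=1),
            encoding="utf-8")


def generate_lexicon(config: GeneratorConfig, aux_rate: float = 0.0) -> EmotionLexicon:
    """Synthetic affect lexicon: ``words_per_category`` unique words per
    category, intensities from ``intensity_dist``, valence-consistent
    polarities, all 7 POS classes cycled through.  With ``aux_rate > 0`` a
    fraction of words carries an auxiliary attribution of a same-valence
    companion category."""
    if config.words_per_category < 1:
        raise ValueError("need at least one word per category")
    rng = np.random.default_rng(config.seed + 1)
    levels = sorted(config.intensity_dist)
    probs = np.array([config.intensity_dist[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    companions = {"Good": "Happy", "Happy": "Good", "Anger": "Disgust",
                  "Disgust": "Anger", "Sadness": "Fear", "Fear": "Sadness",
                  "Surprise": "Good"}
    entries = []
    idx = 0
    base = config.V  # word indices after the neutral vocabulary
    for emotion in EMOTIONS:
        for j in range(config.words_per_category):
            word = _word(base + idx)
            intensity = int(rng.choice(levels, p=probs))
            aux = None
            if aux_rate > 0 and rng.random() < aux_rate:
                comp = companions[emotion]
                aux = Attribution(comp, int(rng.choice(levels, p=probs)),
                                  _POLARITY_OF[comp])
            entries.append(LexiconEntry(
                word=word,
                pos_class=POS_CLASSES[idx % len(POS_CLASSES)],
                emotion=emotion,
                intensity=intensity,
                polarity=_POLARITY_OF[emotion],
                subcategory=f"{emotion.lower()}-{j % 3 + 1}",
                aux=aux,
            ))
            idx += 1
    return EmotionLexicon(entries)


def generate_stopwords(config: GeneratorConfig) -> frozenset[str]:
    base = config.V + 7 * config.words_per_category
    return frozenset(_word(base + i) for i in range(config.n_stopwords))


def _planted_phi(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """K_true planted topic-word rows over the neutral vocabulary: a shared
    block of round(overlap·V) words plus near-equal disjoint blocks."""
    V, K = config.V, config.K_true
    n_shared = int(round(config.vocab_overlap * V))
    own = np.array_split(np.arange(n_shared, V), K)
    phi = np.zeros((K, V))
    for k in range(K):
        support = np.concatenate([np.arange(n_shared), own[k]]).astype(int)
        weights = rng.dirichlet(np.full(len(support), config.topic_beta))
        phi[k, support] = weights
    return phi


def generate_corpus(config: GeneratorConfig,
                    lexicon: EmotionLexicon | None = None) -> SyntheticCorpus:
    """Generate a corpus with planted topics, emotions, and timestamps.

    Per document: θ ~ Dirichlet(topic_alpha); background tokens from the
    planted φ rows; with probability 1 − neutral_rate a dominant category is
    drawn from ``emotion_mix`` and 2–4 emotion-word slots are injected, each
    flipped to a uniformly random other category with probability
    ``contamination``.  Stop-word tokens, punctuation and URL noise are
    sprinkled in; the cleaned text is the exact concatenation of the planted
    tokens."""
    rng = np.random.default_rng(config.seed)
    if lexicon is None:
        lexicon = generate_lexicon(config)
    stopwords = generate_stopwords(config)
    stop_list = sorted(stopwords)
    neutral_vocab = [_word(i) for i in range(config.V)]
    phi_true = _planted_phi(config, rng)
    mix_cats = [e for e in EMOTIONS if config.emotion_mix.get(e, 0.0) > 0]
    mix_p = np.array([config.emotion_mix[e] for e in mix_cats])
    mix_p = mix_p / mix_p.sum()
    words_by_cat = {e: lexicon.words_of(e) for e in EMOTIONS}

    days = config.days()
    day_w = config.day_weights()

    posts: list[RawPost] = []
    truth: dict[str, dict] = {}
    lo, hi = config.doc_length
    elo, ehi = config.emo_words_per_doc
    for i in range(config.n_docs):
        theta = rng.dirichlet(np.full(config.K_true, config.topic_alpha))
        L = int(rng.integers(lo, hi + 1))
        topics = rng.choice(config.K_true, size=L, p=theta)
        tokens = [neutral_vocab[int(rng.choice(config.V, p=phi_true[t]))]
                  for t in topics]
        # stop-word sprinkle
        for _ in range(int(rng.binomial(L, config.stopword_rate))):
            tokens.append(stop_list[int(rng.integers(len(stop_list)))])
        # emotion injection
        label: str | None = None
        if rng.random() >= config.neutral_rate:
            label = mix_cats[int(rng.choice(len(mix_cats), p=mix_p))]
            n_emo = int(rng.integers(elo, ehi + 1))
            for _ in range(n_emo):
                cat = label
                if config.contamination > 0 and rng.random() < config.contamination:
                    others = [e for e in EMOTIONS if e != label]
                    cat = others[int(rng.integers(len(others)))]
                pool = words_by_cat[cat]
                tokens.append(pool[int(rng.integers(len(pool)))])
        order = rng.permutation(len(tokens))
        tokens = [tokens[j] for j in order]
        text = "".join(tokens)
        if rng.random() < config.url_noise_rate:
            text = text + "http://t.cn/" + "".join(
                rng.choice(list("abcdefgh123"), size=6))
        if rng.random() < config.punct_noise_rate:
            text = text + "!!"
        day = days[int(rng.choice(len(days), p=day_w))]
        sec = int(rng.integers(0, 86400))
        ts = f"{day.isoformat()}T{sec // 3600:02d}:{sec % 3600 // 60:02d}:{sec % 60:02d}"
        post_id = f"p{i:06d}"
        posts.append(RawPost(post_id=post_id, timestamp=ts, text=text))
        truth[post_id] = {"emotion": label, "theta": theta.tolist()}

    return SyntheticCorpus(posts=posts, truth=truth, lexicon=lexicon,
                           phi_true=phi_true, stopwords=stopwords,
                           neutral_vocab=neutral_vocab, config=config)


def planted_phi_on_vocab(corpus: SyntheticCorpus,
                         vocabulary: Sequence[str]) -> np.ndarray:
    """Project the planted topic-word rows onto another vocabulary ordering
    (e.g. a fitted model's bag-of-words vocabulary); words outside the
    neutral vocabulary get zero mass.  Rows are not re-normalized."""
    index = {w: i for i, w in enumerate(corpus.neutral_vocab)}
    out = np.zeros((corpus.phi_true.shape[0], len(vocabulary)))
    for j, w in enumerate(vocabulary):
        if w in index:
            out[:, j] = corpus.phi_true[:, index[w]]
    return out


def generate_annotations(
    truth_labels: Sequence[str],
    annotator_error: float,
    seed: int,
    categories: Sequence[str] = EMOTIONS,
) -> tuple[list[str], list[str]]:
    """Two simulated annotators: each copies the truth label and, with
    probability ``annotator_error`` independently per item and per
    annotator, replaces it with a uniformly random *different* category."""
    if not 0.0 <= annotator_error <= 1.0:
        raise ValueError("annotator_error must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[list[str]] = []
    for _ in range(2):
        labels = []
        for lab in truth_labels:
            if rng.random() < annotator_error:
                others = [c for c in categories if c != lab]
                lab = others[int(rng.integers(len(others)))]
            labels.append(lab)
        out.append(labels)
    return out[0], out[1]
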