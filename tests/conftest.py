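import pytest

from emotopic.lexicon import EMOTIONS, Attribution, EmotionLexicon, LexiconEntry
from emotopic.preprocess import preprocess_corpus
from emotopic.synthetic_data import GeneratorConfig, generate_corpus
from emotopic.topic_model import BowCorpus


@pytest.fixture
def toy_lexicon():
    """14 entries, 2 per category; one word carries an auxiliary attribution."""
    words = {
        "Good": [("希望", "verb", 5), ("支持", "verb", 5)],
        "Happy": [("开心", "adj", 5), ("平安", "noun", 7)],
        "Anger": [("抗议", "verb", 5), ("愤怒", "adj", 7)],
        "Disgust": [("无语", "adj", 3), ("讨厌", "verb", 5)],
        "Sadness": [("难过", "adj", 5), ("不幸", "adj", 9)],
        "Surprise": [("惊讶", "adj", 5), ("突然", "adv", 3)],
        "Fear": [("恐慌", "noun", 7), ("害怕", "verb", 5)],
    }
    polarity = {"Good": 1, "Happy": 1, "Anger": 2, "Disgust": 2,
                "Sadness": 2, "Surprise": 3, "Fear": 2}
    entries = []
    for emotion, pairs in words.items():
        for word, pos, inten in pairs:
            aux = Attribution("Happy", 3, 1) if word == "希望" else None
            entries.append(LexiconEntry(word=word, pos_class=pos,
                                        emotion=emotion, intensity=inten,
                                        polarity=polarity[emotion],
                                        subcategory=f"{emotion.lower()}-1",
                                        aux=aux))
    return EmotionLexicon(entries)


def make_topic_bundle(seed: int, n_docs: int = 500):
    """Purely thematic corpus (no emotion words) on the 3-topic, 300-word
    disjoint-vocabulary study conditions, preprocessed to bag-of-words."""
    cfg = GeneratorConfig(seed=seed, n_docs=n_docs, K_true=3, V=300,
                          vocab_overlap=0.0, neutral_rate=1.0)
    corpus = generate_corpus(cfg)
    docs, _ = preprocess_corpus(
        corpus.posts, corpus.lexicon, stopwords=corpus.stopwords,
        user_dict=set(corpus.neutral_vocab) | corpus.stopwords)
    bow = BowCorpus.from_tokenized([d.tokens for d in docs])
    return corpus, docs, bow


@pytest.fixture(scope="session")
def topic_bundle():
    return make_topic_bundle(seed=0)
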