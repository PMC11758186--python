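"""Cleaning, validity filtering, segmentation, and stop-word removal.

Raw microblog posts are noisy: URLs, HTML tags, punctuation, emoticons.
Cleaning keeps only Unicode letters (which includes CJK ideographs) and
digits.  Posts whose cleaned text is shorter than a minimum character count
(default 10, counted in code points) are treated as invalid and dropped.

Segmentation is deterministic forward maximum matching (FMM) against the
lexicon vocabulary plus an optional user dictionary: at each position the
longest dictionary word starting there is emitted, otherwise a single
character.  FMM is lossless — the concatenation of the tokens reproduces
the input — and self-contained; an external segmenter can be substituted
by any callable with the same signature.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .lexicon import EmotionLexicon

_URL_RE = re.compile(
    r"(?:https?|ftp)://[^\s一-鿿]+|www\.[^\s一-鿿]+",
    re.IGNORECASE,
)
_TAG_RE = re.compile(r"<[^<>]*?>")


@dataclass(frozen=True)
class RawPost:
    post_id: str
    timestamp: str  # ISO-8601
    text: str


@dataclass(frozen=True)
class TokenizedDoc:
    post_id: str
    timestamp: str
    tokens: tuple[str, ...]
    cleaned_length: int


def clean_text(text: str) -> str:
    """Strip HTML tags and URLs, then drop every character that is not a
    Unicode letter or digit.  Idempotent; order of surviving characters is
    preserved."""
    text = _TAG_RE.sub("", text)
    text = _URL_RE.sub("", text)
    return "".join(ch for ch in text if ch.isalnum())


def filter_valid(
    posts: Sequence[RawPost], min_chars: int = 10, on_cleaned: bool = True,
) -> tuple[list[RawPost], int]:
    """Drop posts considered invalid text: fewer than ``min_chars``
    characters (code points), counted on the cleaned text by default."""
    if min_chars < 0:
        raise ValueError("min_chars must be >= 0")
    retained = []
    for p in posts:
        n = len(clean_text(p.text)) if on_cleaned else len(p.text)
        if n >= min_chars:
            retained.append(p)
    return retained, len(posts) - len(retained)


def tokenize(
    text: str,
    lexicon: EmotionLexicon | Iterable[str],
    user_dict: Iterable[str] | None = None,
) -> list[str]:
    """Forward-maximum-matching segmentation over the lexicon vocabulary
    (plus ``user_dict``).  ``"".join(result) == text`` always holds."""
    vocab = set(lexicon.vocabulary if isinstance(lexicon, EmotionLexicon) else lexicon)
    if user_dict:
        vocab |= set(user_dict)
    max_len = max((len(w) for w in vocab), default=1)
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        match = text[i]
        for length in range(min(max_len, n - i), 1, -1):
            cand = text[i:i + length]
            if cand in vocab:
                match = cand
                break
        tokens.append(match)
        i += len(match)
    return tokens


def remove_stopwords(tokens: Sequence[str], stopwords: Iterable[str]) -> list[str]:
    sw = set(stopwords)
    return [t for t in tokens if t not in sw]


def preprocess_corpus(
    posts: Sequence[RawPost],
    lexicon: EmotionLexicon,
    stopwords: Iterable[str] = (),
    min_chars: int = 10,
    user_dict: Iterable[str] | None = None,
    tokenizer: Callable[[str], list[str]] | None = None,
) -> tuple[list[TokenizedDoc], int]:
    """Run clean → validity filter → segment → stop-word removal.

    Returns the retained tokenized documents (input order preserved) and the
    number of dropped posts.  Fully deterministic.
    """
    retained, dropped = filter_valid(posts, min_chars=min_chars)
    docs = []
    for p in retained:
        cleaned = clean_text(p.text)
        toks = tokenizer(cleaned) if tokenizer else tokenize(cleaned, lexicon, user_dict)
        toks = remove_stopwords(toks, stopwords)
        docs.append(TokenizedDoc(
            post_id=p.post_id, timestamp=p.timestamp,
            tokens=tuple(toks), cleaned_length=len(cleaned)))
    return docs, dropped


# ---------------------------------------------------------------------------
# corpus I/O


def read_corpus_jsonl(path: str | Path) -> list[RawPost]:
    posts = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            posts.append(RawPost(str(obj["post_id"]), str(obj["timestamp"]), obj["text"]))
    return posts


def write_corpus_jsonl(posts: Sequence[RawPost], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps(
                {"post_id": p.post_id, "timestamp": p.timestamp, "text": p.text},
                ensure_ascii=False) + "\n")


def read_corpus_csv(path: str | Path) -> list[RawPost]:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return [RawPost(str(r["post_id"]), str(r["timestamp"]), r["text"]) for r in reader]


def write_corpus_csv(posts: Sequence[RawPost], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["post_id", "timestamp", "text"])
        for p in posts:
            writer.writerow([p.post_id, p.timestamp, p.text])


def read_corpus(path: str | Path) -> list[RawPost]:
    """Dispatch on extension: ``.jsonl`` or ``.csv``."""
    path = Path(path)
    if path.suffix == ".jsonl":
        return read_corpus_jsonl(path)
    if path.suffix == ".csv":
        return read_corpus_csv(path)
    raise ValueError(f"unsupported corpus format {path.suffix!r} (use .jsonl or .csv)")


def write_tokenized_jsonl(docs: Sequence[TokenizedDoc], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps(
                {"post_id": d.post_id, "timestamp": d.timestamp,
                 "tokens": list(d.tokens), "cleaned_length": d.cleaned_length},
                ensure_ascii=False) + "\n")


def read_tokenized_jsonl(path: str | Path) -> list[TokenizedDoc]:
    docs = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            docs.append(TokenizedDoc(
                str(obj["post_id"]), str(obj["timestamp"]),
                tuple(obj["tokens"]), int(obj["cleaned_length"])))
    return docs
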