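"""Affect lexicon and stop-word list handling.

The lexicon follows the structure of the DUTIR-style affective ontology:
each word carries a part-of-speech class, one of seven emotion categories
(Good, Happy, Anger, Disgust, Sadness, Surprise, Fear), an optional
subcategory label, an intensity level in {1, 3, 5, 7, 9} (9 strongest),
and a polarity code (0 neutral, 1 positive, 2 negative, 3 both).  A word
may additionally carry one auxiliary (emotion, intensity, polarity)
attribution.

The licensed resource itself is not shipped; this module defines the
tabular dialect it can be mapped onto (UTF-8 TSV/CSV, one header row) and
validates every row on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

#: Canonical emotion categories, in the fixed tie-break / reporting order.
EMOTIONS: tuple[str, ...] = (
    "Good", "Happy", "Anger", "Disgust", "Sadness", "Surprise", "Fear",
)

POS_CLASSES: tuple[str, ...] = (
    "noun", "verb", "adj", "adv", "network_word", "idiom", "prep_phrase",
)

INTENSITY_LEVELS = frozenset({1, 3, 5, 7, 9})
POLARITY_CODES = frozenset({0, 1, 2, 3})

#: Maps alternative category spellings (including the native single-character
#: DUTIR major-class codes) onto the canonical English tokens.  Extend via the
#: ``aliases`` argument of :func:`load_lexicon` for other encodings.
DEFAULT_CATEGORY_ALIASES: dict[str, str] = {
    **{e.lower(): e for e in EMOTIONS},
    **{e.upper(): e for e in EMOTIONS},
    "乐": "Happy", "好": "Good", "怒": "Anger", "哀": "Sadness",
    "惧": "Fear", "恶": "Disgust", "惊": "Surprise",
}

DEFAULT_POS_ALIASES: dict[str, str] = {
    "adjective": "adj", "adverb": "adv", "nw": "network_word",
    "prep phrase": "prep_phrase",
}

REQUIRED_COLUMNS = ("word", "pos_class", "emotion", "intensity", "polarity")
ALL_COLUMNS = REQUIRED_COLUMNS[:3] + ("subcategory",) + REQUIRED_COLUMNS[3:] + (
    "aux_emotion", "aux_intensity", "aux_polarity",
)


class LexiconFormatError(ValueError):
    """Structural problem with a lexicon file (missing columns, bad dialect)."""


class LexiconValidationError(ValueError):
    """A row violates the lexicon domain constraints."""


@dataclass(frozen=True)
class Attribution:
    """A single (emotion, intensity, polarity) attribution of a word."""

    emotion: str
    intensity: int
    polarity: int

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise LexiconValidationError(
                f"unknown emotion category {self.emotion!r}; expected one of {EMOTIONS}")
        if self.intensity not in INTENSITY_LEVELS:
            raise LexiconValidationError(
                f"intensity {self.intensity!r} not in {sorted(INTENSITY_LEVELS)}")
        if self.polarity not in POLARITY_CODES:
            raise LexiconValidationError(
                f"polarity {self.polarity!r} not in {sorted(POLARITY_CODES)}")


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    pos_class: str
    emotion: str
    intensity: int
    polarity: int
    subcategory: str | None = None
    aux: Attribution | None = None

    def __post_init__(self) -> None:
        if not self.word or any(ch.isspace() for ch in self.word):
            raise LexiconValidationError(
                f"word must be non-empty with no whitespace, got {self.word!r}")
        if self.pos_class not in POS_CLASSES:
            raise LexiconValidationError(
                f"unknown pos_class {self.pos_class!r}; expected one of {POS_CLASSES}")
        # Reuse Attribution validation for the primary triple.
        Attribution(self.emotion, self.intensity, self.polarity)

    @property
    def primary(self) -> Attribution:
        return Attribution(self.emotion, self.intensity, self.polarity)


class EmotionLexicon:
    """An in-memory affect lexicon keyed by word.

    One primary record per word; a second, auxiliary attribution may ride on
    the same entry.  Duplicate words are rejected at construction.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        for e in entries:
            if e.word in self._entries:
                raise LexiconValidationError(f"duplicate word {e.word!r}")
            self._entries[e.word] = e

    @property
    def entries(self) -> Mapping[str, LexiconEntry]:
        return self._entries

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._entries)

    @property
    def max_word_length(self) -> int:
        return max((len(w) for w in self._entries), default=0)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, word: str) -> bool:
        return word in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmotionLexicon):
            return NotImplemented
        return self._entries == other._entries

    def lookup(self, token: str) -> tuple[Attribution, ...]:
        """Return the attributions of ``token``: primary first, then the
        auxiliary one if present; empty tuple for unknown tokens."""
        entry = self._entries.get(token)
        if entry is None:
            return ()
        if entry.aux is None:
            return (entry.primary,)
        return (entry.primary, entry.aux)

    def words_of(self, emotion: str) -> list[str]:
        """All words whose primary category is ``emotion``, sorted."""
        if emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion category {emotion!r}")
        return sorted(w for w, e in self._entries.items() if e.emotion == emotion)


def _canon(value: str, table: Mapping[str, str]) -> str:
    return table.get(value, value)


def load_lexicon(
    path: str | Path,
    dialect: str = "tsv",
    aliases: Mapping[str, str] | None = None,
) -> EmotionLexicon:
    """Load and validate a lexicon from a TSV/CSV file.

    The header must name at least ``word, pos_class, emotion, intensity,
    polarity``; ``subcategory`` and the ``aux_*`` triple are optional and may
    be blank.  ``aliases`` extends the default category alias table, letting
    a resource's native category codes map onto the canonical seven.

    Raises :class:`LexiconFormatError` for structural problems and
    :class:`LexiconValidationError` (naming the offending row) for domain
    violations.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    cat_aliases = dict(DEFAULT_CATEGORY_ALIASES)
    if aliases:
        cat_aliases.update(aliases)

    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise LexiconFormatError(f"{path}: empty file, no header row")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise LexiconFormatError(f"{path}: missing required column(s) {missing}")
        entries = []
        for rownum, row in enumerate(reader, start=2):  # header is line 1
            try:
                entries.append(_parse_row(row, cat_aliases))
            except (LexiconValidationError, ValueError) as exc:
                raise LexiconValidationError(f"{path}: row {rownum}: {exc}") from exc
    try:
        return EmotionLexicon(entries)
    except LexiconValidationError as exc:
        raise LexiconValidationError(f"{path}: {exc}") from exc


def _parse_row(row: Mapping[str, str], cat_aliases: Mapping[str, str]) -> LexiconEntry:
    def get(col: str) -> str:
        return (row.get(col) or "").strip()

    aux = None
    if get("aux_emotion"):
        aux = Attribution(
            emotion=_canon(get("aux_emotion"), cat_aliases),
            intensity=int(get("aux_intensity")),
            polarity=int(get("aux_polarity")),
        )
    return LexiconEntry(
        word=get("word"),
        pos_class=_canon(get("pos_class"), DEFAULT_POS_ALIASES),
        emotion=_canon(get("emotion"), cat_aliases),
        intensity=int(get("intensity")),
        polarity=int(get("polarity")),
        subcategory=get("subcategory") or None,
        aux=aux,
    )


def write_lexicon(lexicon: EmotionLexicon, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``lexicon`` so that :func:`load_lexicon` round-trips it exactly."""
    delim = "\t" if dialect == "tsv" else ","
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(ALL_COLUMNS)
        for word in sorted(lexicon.entries):
            e = lexicon.entries[word]
            writer.writerow([
                e.word, e.pos_class, e.emotion, e.subcategory or "",
                e.intensity, e.polarity,
                e.aux.emotion if e.aux else "",
                e.aux.intensity if e.aux else "",
                e.aux.polarity if e.aux else "",
            ])


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stop-word list: UTF-8, one token per line, ``#`` comments."""
    tokens = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens.add(line)
    return frozenset(tokens)


def write_stopwords(tokens: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(sorted(set(tokens))) + "\n", encoding="utf-8")
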