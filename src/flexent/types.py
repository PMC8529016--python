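"""Core domain types for the inflectional lexicon pipeline.

The pipeline works on annotated word forms of Italian nouns and
adjectives.  Each word form carries a gender value (feminine or
masculine), a number value (singular or plural), and a corpus token
frequency.  Gender and number jointly define the four feature
combinations F.SG, F.PL, M.SG, M.PL that all downstream distributions
are conditioned on.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "Pos",
    "Gender",
    "Number",
    "Grade",
    "FeatureCombo",
    "COMBO_ORDER",
    "LexEntry",
    "Lexicon",
    "normalize_form",
]


class Pos(str, Enum):
    """Part of speech covered by the analysis."""

    NOUN = "noun"
    ADJECTIVE = "adjective"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Gender(str, Enum):
    F = "F"
    M = "M"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Number(str, Enum):
    SG = "SG"
    PL = "PL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Grade(str, Enum):
    """Adjective grade; carried as metadata only."""

    POSITIVE = "positive"
    SUPERLATIVE = "superlative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class FeatureCombo:
    """One of the four gender x number cells (F.SG, F.PL, M.SG, M.PL)."""

    gender: Gender
    number: Number

    def __str__(self) -> str:
        return f"{self.gender.value}.{self.number.value}"

    @classmethod
    def parse(cls, text: str) -> "FeatureCombo":
        g, n = text.strip().split(".")
        return cls(Gender(g), Number(n))


#: Fixed category order used by every report table.
COMBO_ORDER: tuple[FeatureCombo, ...] = (
    FeatureCombo(Gender.F, Number.PL),
    FeatureCombo(Gender.F, Number.SG),
    FeatureCombo(Gender.M, Number.PL),
    FeatureCombo(Gender.M, Number.SG),
)


def normalize_form(form: str) -> str:
    """Normalize a surface form: Unicode NFC plus lowercase folding.

    Ending extraction operates on the final character, so composed and
    decomposed accented vowels (à, è, ù) must compare equal.
    """
    return unicodedata.normalize("NFC", form).casefold().strip()


@dataclass(frozen=True)
class LexEntry:
    """One annotated inflected word form with its corpus token frequency."""

    form: str
    lemma: str
    pos: Pos
    gender: Gender
    number: Number
    token_freq: int
    grade: Optional[Grade] = None
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("LexEntry.form must be non-empty")
        if self.token_freq < 0:
            raise ValueError(
                f"LexEntry.token_freq must be >= 0, got {self.token_freq!r} "
                f"for form {self.form!r}"
            )

    @property
    def combo(self) -> FeatureCombo:
        return FeatureCombo(self.gender, self.number)

    @property
    def key(self) -> tuple:
        """Identity key: no two entries of a lexicon may share it."""
        return (self.form, self.pos.value, self.gender.value,
                self.number.value, self.lemma)

    def with_freq(self, token_freq: int) -> "LexEntry":
        return replace(self, token_freq=token_freq)


#: Projection used for round-trip equality of lexica.
_PROJECTION = ("form", "lemma", "pos", "gender", "number", "token_freq", "grade")


@dataclass
class Lexicon:
    """An ordered collection of annotated word forms.

    ``corpus_size`` is the token count of the source corpus, used for
    per-million frequency standardization; it is a property of the
    corpus the frequencies came from, not the sum of the lexicon's own
    token frequencies.
    """

    entries: list[LexEntry] = field(default_factory=list)
    corpus_size: int = 1
    dialect: str = "flexit"

    def __post_init__(self) -> None:
        if self.corpus_size <= 0:
            raise ValueError(f"corpus_size must be > 0, got {self.corpus_size}")
        seen: set[tuple] = set()
        for e in self.entries:
            if e.key in seen:
                raise ValueError(
                    f"duplicate lexicon entry key {e.key!r}; merge duplicates "
                    "before constructing a Lexicon"
                )
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexEntry]:
        return iter(self.entries)

    def subset(self, pos: Pos) -> "Lexicon":
        return Lexicon(
            [e for e in self.entries if e.pos is pos],
            corpus_size=self.corpus_size,
            dialect=self.dialect,
        )

    @property
    def total_tokens(self) -> int:
        """Sum of token frequencies over all entries.

        Homograph entries each carry the full undivided frequency of
        their shared form, so this sum can exceed the number of corpus
        occurrences; it is the conserved quantity of read/write/merge.
        """
        return sum(e.token_freq for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        """Entries as a DataFrame (one row per entry, enum values as str)."""
        return pd.DataFrame(
            {
                "form": [e.form for e in self.entries],
                "lemma": [e.lemma for e in self.entries],
                "pos": [e.pos.value for e in self.entries],
                "gender": [e.gender.value for e in self.entries],
                "number": [e.number.value for e in self.entries],
                "token_freq": [e.token_freq for e in self.entries],
                "grade": [e.grade.value if e.grade else "" for e in self.entries],
            }
        )

    def projection(self) -> set[tuple]:
        """Order-independent view on the fields preserved by round trips."""
        out = set()
        for e in self.entries:
            out.add((e.form, e.lemma, e.pos.value, e.gender.value,
                     e.number.value, e.token_freq,
                     e.grade.value if e.grade else ""))
        return out

    def equals_projection(self, other: "Lexicon") -> bool:
        return self.projection() == other.projection()

    @staticmethod
    def from_entries(entries: Iterable[LexEntry], corpus_size: int,
                     dialect: str = "flexit") -> "Lexicon":
        return Lexicon(list(entries), corpus_size=corpus_size, dialect=dialect)
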