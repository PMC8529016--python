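"""Type/token distributions over feature values and their Shannon entropy.

Two families of distributions quantify form-value transparency:

* per *ending* — how the word forms sharing a final vowel (-a, -e, -i,
  -o) distribute over the four feature combinations F.PL, F.SG, M.PL,
  M.SG;
* per *declensional class* — how a class's lemmas distribute over
  gender (nouns, two-cell paradigms, max 1 bit) or how its attested
  cells distribute over the four combinations (adjectives, four-cell
  paradigms, max 2 bits).

Each distribution is summarized by its Shannon entropy in bits,
H = -sum p_v log2 p_v: low entropy means the ending (or class) reliably
signals one feature value, i.e. a transparent form-value mapping.
Counts follow the ambiguity counting policy: type counts include
ambiguous forms once per attested combination, token counts cover
non-ambiguous forms only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ambiguity import apply_counting_policy, detect_ambiguous_forms
from .paradigm_builder import (
    CORE_ENDINGS,
    Paradigm,
    build_labeled_paradigms,
    extract_ending,
)
from .types import COMBO_ORDER, Gender, LexEntry, Lexicon, Number, Pos

__all__ = [
    "ValueDistribution",
    "EntropyRow",
    "shannon_entropy",
    "ending_distribution",
    "class_distribution",
    "render_entropy_table",
    "entropy_rows",
    "AnalysisReport",
    "analyze",
]

#: Category order of the gender axis used by noun class tables.
GENDER_ORDER = (Gender.F.value, Gender.M.value)
#: Category order of the feature-combination axis.
COMBO_LABELS = tuple(str(c) for c in COMBO_ORDER)


def shannon_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy of a count vector, in bits.

    H = -sum over positive counts of (c/T) * log2(c/T); zero counts
    contribute nothing.  All-zero (or empty) input has no defined
    distribution and raises ``ValueError``.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero count vector")
    p = arr[arr > 0] / total
    h = float(-(p * np.log2(p)).sum())
    return 0.0 if h == 0 else h


@dataclass(frozen=True)
class ValueDistribution:
    """Counts over feature-value categories under one conditioner.

    ``kind`` says what conditions the distribution (an ending or a
    declensional class), ``label`` names it, and ``unit`` says whether
    the counts are types or tokens.
    """

    kind: str                      # "ending" | "class"
    label: str
    pos: Pos
    unit: str                      # "type" | "token"
    categories: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.counts):
            raise ValueError("categories and counts must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> tuple[float, ...]:
        t = self.total
        if t == 0:
            return tuple(0.0 for _ in self.counts)
        return tuple(c / t for c in self.counts)

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    def entropy(self) -> Optional[float]:
        """H in bits, or None for an empty distribution."""
        if self.is_empty:
            return None
        return shannon_entropy(self.counts)


@dataclass(frozen=True)
class EntropyRow:
    """One report row: a distribution plus its entropy in bits."""

    distribution: ValueDistribution
    H: Optional[float]

    @classmethod
    def from_distribution(cls, dist: ValueDistribution) -> "EntropyRow":
        return cls(distribution=dist, H=dist.entropy())


def entropy_rows(dists: Iterable[ValueDistribution]) -> list[EntropyRow]:
    return [EntropyRow.from_distribution(d) for d in dists]


def _combo_counts(pairs: Iterable[tuple]) -> dict:
    counts: dict = {}
    for combo, value in pairs:
        counts[combo] = counts.get(combo, 0) + value
    return counts


def ending_distribution(entries: Sequence[LexEntry], pos: Pos,
                        unit: str) -> list[ValueDistribution]:
    """Distributions over the four combos, one per ending a/e/i/o.

    ``entries`` must already be filtered by the counting policy
    matching ``unit`` (all entries for types, non-ambiguous entries for
    tokens).  Types count distinct (form, combination) pairs; tokens
    sum each form's frequency once per combination.  Forms with endings
    outside {a, e, i, o} are collected into a fifth remainder
    distribution labelled ``other``; slicing ``[:4]`` gives the core
    report rows.
    """
    if unit not in ("type", "token"):
        raise ValueError(f"unit must be 'type' or 'token', got {unit!r}")

    seen: set[tuple] = set()
    per_ending: dict[str, list[tuple]] = {e: [] for e in CORE_ENDINGS}
    per_ending["other"] = []
    for e in entries:
        if e.pos is not pos:
            continue
        key = (e.form, e.gender, e.number)
        if key in seen:      # same (form, combo) under several lemmas
            continue
        seen.add(key)
        ending = extract_ending(e.form)
        bucket = ending.value if ending.is_core else "other"
        value = 1 if unit == "type" else e.token_freq
        per_ending[bucket].append((e.combo, value))

    out = []
    for label in (*CORE_ENDINGS, "other"):
        counts = _combo_counts(per_ending[label])
        out.append(
            ValueDistribution(
                kind="ending", label=label, pos=pos, unit=unit,
                categories=COMBO_LABELS,
                counts=tuple(int(counts.get(c, 0)) for c in COMBO_ORDER),
            )
        )
    return out


def _entry_paradigm_map(paradigms: Sequence[Paradigm]) -> dict[tuple, int]:
    mapping: dict[tuple, int] = {}
    for i, p in enumerate(paradigms):
        for e in p.entries:
            mapping[e.key] = i
    return mapping


def class_distribution(paradigms: Sequence[Paradigm],
                       entries: Sequence[LexEntry],
                       pos: Pos, unit: str) -> list[ValueDistribution]:
    """Distributions per declensional class.

    Nouns: counts over gender {F, M} — types count lemmas by their
    lemma-level gender; tokens sum the frequencies of the class's
    (non-ambiguous) entries by the gender of each attested form, so a
    gender-changing plural's tokens land on the plural's own gender.
    One-cell noun paradigms (NA labels) are not classes and are left
    out.  Adjectives: counts over the four feature combinations —
    types count attested (lemma, combination) cells, tokens sum
    frequencies per combination; defective (NA-labelled) classes are
    regular rows.

    ``entries`` is the token-side entry list from the counting policy;
    it is ignored for ``unit='type'`` noun tables.  Classes are ordered
    by descending total, then label.
    """
    if unit not in ("type", "token"):
        raise ValueError(f"unit must be 'type' or 'token', got {unit!r}")

    pool = [p for p in paradigms if p.pos is pos]
    if pos is Pos.NOUN:
        pool = [p for p in pool if p.class_label and "NA" not in p.class_label]
    pool = [p for p in pool if p.class_label]

    if pos is Pos.NOUN:
        categories = GENDER_ORDER
        counts: dict[str, dict[str, int]] = {}
        if unit == "type":
            for p in pool:
                row = counts.setdefault(p.class_label, {})
                g = p.gender_key.value if p.gender_key else Gender.M.value
                row[g] = row.get(g, 0) + 1
        else:
            emap = _entry_paradigm_map(pool)
            for e in entries:
                if e.pos is not pos:
                    continue
                i = emap.get(e.key)
                if i is None:
                    continue
                row = counts.setdefault(pool[i].class_label, {})
                row[e.gender.value] = row.get(e.gender.value, 0) + e.token_freq
            for p in pool:     # classes emptied by the token policy still show
                counts.setdefault(p.class_label, {})
        axis = [Gender.F.value, Gender.M.value]
    else:
        categories = COMBO_LABELS
        counts = {}
        if unit == "type":
            for p in pool:
                row = counts.setdefault(p.class_label, {})
                for combo in p.adj_cells:
                    row[str(combo)] = row.get(str(combo), 0) + 1
        else:
            emap = _entry_paradigm_map(pool)
            for e in entries:
                if e.pos is not pos:
                    continue
                i = emap.get(e.key)
                if i is None:
                    continue
                row = counts.setdefault(pool[i].class_label, {})
                c = str(e.combo)
                row[c] = row.get(c, 0) + e.token_freq
            for p in pool:
                counts.setdefault(p.class_label, {})
        axis = list(COMBO_LABELS)

    dists = [
        ValueDistribution(
            kind="class", label=label, pos=pos, unit=unit,
            categories=tuple(categories),
            counts=tuple(int(counts[label].get(c, 0)) for c in axis),
        )
        for label in counts
    ]
    dists.sort(key=lambda d: (-d.total, d.label))
    return dists


def _fmt4(x: float) -> str:
    """Four decimals, ties rounded half away from zero."""
    return str(Decimal(repr(x)).quantize(Decimal("0.0001"),
                                         rounding=ROUND_HALF_UP))


def render_entropy_table(rows: Sequence[EntropyRow],
                         path: Union[str, Path]) -> pd.DataFrame:
    """Write rows as a TSV report table; returns the rendered frame.

    Per row: the conditioner label, one count column and one
    parenthesized row-internal proportion column per category, the
    total, and H to four decimals ('-' for an empty row).  Row order is
    taken as given (the distribution builders already order endings
    alphabetically and classes by descending total).
    """
    rendered = []
    columns: list[str] = []
    for row in rows:
        d = row.distribution
        rec = {d.kind: d.label}
        for cat, cnt in zip(d.categories, d.counts):
            rec[cat] = cnt
        for cat, p in zip(d.categories, d.proportions):
            rec[f"p_{cat}"] = f"({_fmt4(p)})" if not d.is_empty else "(-)"
        rec["total"] = d.total
        rec["H"] = _fmt4(row.H) if row.H is not None else "-"
        rendered.append(rec)
        if not columns:
            columns = list(rec)
    frame = pd.DataFrame(rendered, columns=columns or None)
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8",
                 lineterminator="\n")
    return frame


@dataclass
class AnalysisReport:
    """Everything the pipeline computes for one lexicon."""

    lexicon: Lexicon
    paradigms: list[Paradigm]
    records: dict[Pos, set]
    pattern_tables: dict[Pos, pd.DataFrame]
    tables: dict[tuple[str, str, str], list[EntropyRow]]
    #       (pos value, "ending"|"class", "type"|"token") -> rows

    def entropy_summary(self) -> dict[str, float]:
        """Flat {pos_by_label_unit: H} mapping over all non-empty rows."""
        out: dict[str, float] = {}
        for (pos, by, unit), rows in sorted(self.tables.items()):
            for row in rows:
                if row.H is None:
                    continue
                label = row.distribution.label.replace(" ", "+")
                out[f"{pos}_{by}_{label}_{unit}"] = row.H
        return out


def analyze(lexicon: Lexicon) -> AnalysisReport:
    """Run the full pipeline: paradigms, ambiguity, all entropy tables."""
    from .ambiguity import tabulate_patterns

    paradigms = build_labeled_paradigms(lexicon)
    records: dict[Pos, set] = {}
    pattern_tables: dict[Pos, pd.DataFrame] = {}
    tables: dict[tuple[str, str, str], list[EntropyRow]] = {}
    for pos in (Pos.NOUN, Pos.ADJECTIVE):
        recs = detect_ambiguous_forms(lexicon, pos)
        records[pos] = recs
        pattern_tables[pos] = tabulate_patterns(recs)
        counting = apply_counting_policy(lexicon, recs, pos)
        for unit, entries in (("type", counting.type_entries),
                              ("token", counting.token_entries)):
            tables[(pos.value, "ending", unit)] = entropy_rows(
                ending_distribution(entries, pos, unit)
            )
            tables[(pos.value, "class", unit)] = entropy_rows(
                class_distribution(paradigms, entries, pos, unit)
            )
    return AnalysisReport(lexicon=lexicon, paradigms=paradigms,
                          records=records, pattern_tables=pattern_tables,
                          tables=tables)
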