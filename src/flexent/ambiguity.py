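"""Within-POS homograph detection and the type/token counting policy.

A surface form is *ambiguous* when, within one part of speech, it is
attested under two or more distinct gender x number combinations —
whether through incidental lemma homography (latte), declensional-class
intersection (cameriere: M.SG of e_i vs F.PL of a_e), or invariance
(portavoce, attested in all four combinations).  All such forms are
pooled regardless of the factor that produced them.  Homography across
parts of speech (manifesto noun vs adjective) is never ambiguity here,
because corpus frequencies are tagged at the POS level and therefore
carry no cross-POS confound.

Because the token frequency of an ambiguous form cannot be divided
among its feature combinations, the counting policy keeps ambiguous
forms in the *type* counts (one type per attested combination) but
drops their tokens entirely: token tables are computed over
non-ambiguous forms only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import FeatureCombo, LexEntry, Lexicon, Pos

__all__ = [
    "AmbiguityRecord",
    "CountingResult",
    "combo_pattern",
    "detect_ambiguous_forms",
    "tabulate_patterns",
    "apply_counting_policy",
    "ambiguity_proportion",
]


def combo_pattern(combos: Iterable[FeatureCombo]) -> str:
    """Canonical pattern string: sorted combo names joined by '-'.

    Lexicographic order of the rendered names (F.PL < F.SG < M.PL <
    M.SG) makes the pattern a function of the combo set alone.
    """
    return "-".join(sorted(str(c) for c in combos))


@dataclass(frozen=True)
class AmbiguityRecord:
    """One surface form attested under >= 2 feature combinations."""

    form: str
    pos: Pos
    combos: frozenset[FeatureCombo]
    member_lemmas: frozenset[str]

    def __post_init__(self) -> None:
        if not 2 <= len(self.combos) <= 4:
            raise ValueError(
                f"AmbiguityRecord needs 2-4 combos, got {len(self.combos)} "
                f"for {self.form!r}"
            )

    @property
    def pattern(self) -> str:
        return combo_pattern(self.combos)

    def identity(self) -> tuple:
        """(form, pos, combo set) triple used for set comparisons."""
        return (self.form, self.pos.value, self.combos)


def detect_ambiguous_forms(lexicon: Lexicon, pos: Pos) -> set[AmbiguityRecord]:
    """Find every form of ``pos`` spanning >= 2 distinct feature combos."""
    by_form: dict[str, list[LexEntry]] = {}
    for e in lexicon:
        if e.pos is pos:
            by_form.setdefault(e.form, []).append(e)

    records: set[AmbiguityRecord] = set()
    for form, entries in by_form.items():
        combos = frozenset(e.combo for e in entries)
        if len(combos) >= 2:
            records.add(
                AmbiguityRecord(
                    form=form,
                    pos=pos,
                    combos=combos,
                    member_lemmas=frozenset(e.lemma for e in entries),
                )
            )
    return records


def tabulate_patterns(records: set[AmbiguityRecord]) -> pd.DataFrame:
    """Count records per ambiguity pattern, with a Total row.

    Patterns are sorted by descending combo-set size, then
    lexicographically, mirroring the layout of the published ambiguity
    tables (four-way invariants first, two-way syncretisms last).
    """
    counts: dict[str, int] = {}
    sizes: dict[str, int] = {}
    for r in records:
        counts[r.pattern] = counts.get(r.pattern, 0) + 1
        sizes[r.pattern] = len(r.combos)
    ordered = sorted(counts, key=lambda p: (-sizes[p], p))
    rows = [{"pattern": p, "n_forms": counts[p]} for p in ordered]
    rows.append({"pattern": "Total", "n_forms": len(records)})
    return pd.DataFrame(rows, columns=["pattern", "n_forms"])


@dataclass
class CountingResult:
    """Entries split by the type/token counting policy.

    ``type_entries`` keeps everything (an ambiguous form contributes
    one type per attested combination); ``token_entries`` keeps only
    entries whose form is not ambiguous.  ``ambiguous_forms`` records
    which forms were excluded from the token side.
    """

    type_entries: list[LexEntry]
    token_entries: list[LexEntry]
    ambiguous_forms: frozenset[str]


def apply_counting_policy(
    lexicon: Lexicon,
    records: set[AmbiguityRecord],
    pos: Optional[Pos] = None,
) -> CountingResult:
    """Split entries into type-counted and token-counted sets.

    ``records`` must be the detection output for the same POS.  When
    ``pos`` is given, only entries of that POS are considered (the
    policy is applied per part of speech).
    """
    ambiguous = frozenset(r.form for r in records)
    entries = [e for e in lexicon if pos is None or e.pos is pos]
    type_entries = list(entries)
    token_entries = [e for e in entries if e.form not in ambiguous]
    if entries and not token_entries:
        import logging

        logging.getLogger(__name__).warning(
            "every form is ambiguous; token tables will be empty"
        )
    return CountingResult(type_entries=type_entries,
                          token_entries=token_entries,
                          ambiguous_forms=ambiguous)


def ambiguity_proportion(lexicon: Lexicon, pos: Pos,
                         records: set[AmbiguityRecord]) -> float:
    """Share of distinct forms of ``pos`` that are ambiguous."""
    forms = {e.form for e in lexicon if e.pos is pos}
    if not forms:
        return 0.0
    return len({r.form for r in records}) / len(forms)
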