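"""Reconstruct inflectional paradigms and assign declensional classes.

In Italian the inflectional ending of a noun or adjective is its final
character (orthographically transparent writing system), so endings are
obtained by stripping the last character of each normalized form.
Paradigms are reconstructed by coupling the endings attested for the
same lemma: nouns get a two-cell paradigm over number (a noun lemma is
lexically specified for gender), adjectives a four-cell paradigm over
the gender x number combinations (an adjective's values are imposed by
the noun it agrees with).

Class labels join the endings of the cells: noun classes are
SG_PL pairs (o_i, a_e, e_i, a_i, o_a), plus ``Inv`` for invariant
lemmas, ``o_a_i`` for over-abundant o/a+i plurals, and ``Other`` for
attested-but-non-canonical patterns (sport/sports).  Adjective labels
render the feminine and the masculine SG_PL pair side by side
("a_e o_i", "e_i e_i", "a_NA NA", ...), with NA marking unattested
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import FeatureCombo, Gender, Grade, LexEntry, Lexicon, Number, Pos

__all__ = [
    "CORE_ENDINGS",
    "Ending",
    "Paradigm",
    "extract_ending",
    "build_paradigms",
    "assign_noun_class",
    "assign_adjective_class",
    "label_paradigms",
    "build_labeled_paradigms",
    "parse_class_label",
    "NOUN_CANONICAL_CLASSES",
]

#: The four endings the report tables are restricted to.
CORE_ENDINGS: tuple[str, ...] = ("a", "e", "i", "o")

#: Canonical two-cell noun classes: (SG ending, PL ending) -> label.
NOUN_CANONICAL_CLASSES: dict[tuple[str, str], str] = {
    ("o", "i"): "o_i",
    ("a", "e"): "a_e",
    ("e", "i"): "e_i",
    ("a", "i"): "a_i",
    ("o", "a"): "o_a",
}


@dataclass(frozen=True)
class Ending:
    """The final character of a form; OTHER if outside {a, e, i, o}."""

    value: str

    @property
    def is_core(self) -> bool:
        return self.value in CORE_ENDINGS

    def __str__(self) -> str:
        return self.value


def extract_ending(form: str) -> Ending:
    """Strip the last character of a (normalized, non-empty) word form."""
    if not form:
        raise ValueError("cannot extract the ending of an empty form")
    return Ending(form[-1])


@dataclass
class Paradigm:
    """A lemma's attested cells plus its declensional-class label.

    For nouns the cells map number values to the attested (form, ending)
    pairs — normally one pair each, more under over-abundance.  For
    adjectives the cells map each of the four feature combinations to a
    single (form, ending) pair.  ``gender_key`` is the lemma-level
    gender of a noun paradigm (for gender-changing plurals like
    uovo/uova it is the gender of the singular).
    """

    lemma: str
    pos: Pos
    gender_key: Optional[Gender]
    noun_cells: dict[Number, list[tuple[str, Ending]]] = field(default_factory=dict)
    adj_cells: dict[FeatureCombo, tuple[str, Ending]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    class_label: Optional[str] = None
    entries: list[LexEntry] = field(default_factory=list)

    @property
    def is_invariant(self) -> bool:
        return "Inv" in self.flags

    def attested_combos(self) -> list[FeatureCombo]:
        """Distinct feature combinations attested in this paradigm."""
        return sorted({e.combo for e in self.entries})


def _noun_paradigm(lemma: str, gender_key: Gender,
                   entries: list[LexEntry]) -> Paradigm:
    cells: dict[Number, list[tuple[str, Ending]]] = {}
    for e in sorted(entries, key=lambda x: (x.number.value, -x.token_freq, x.form)):
        pair = (e.form, extract_ending(e.form))
        cells.setdefault(e.number, [])
        if pair not in cells[e.number]:
            cells[e.number].append(pair)
    p = Paradigm(lemma=lemma, pos=Pos.NOUN, gender_key=gender_key,
                 noun_cells=cells, entries=list(entries))
    sg_forms = {f for f, _ in cells.get(Number.SG, [])}
    pl_forms = {f for f, _ in cells.get(Number.PL, [])}
    # Identical singular and plural forms always win as invariance.
    if sg_forms and sg_forms == pl_forms:
        p.flags.add("Inv")
    elif any(len(v) > 1 for v in cells.values()):
        p.flags.add("OverAbundant")
    if not sg_forms or not pl_forms:
        p.flags.add("NA")
    return p


def _build_noun_paradigms(lemma: str, entries: list[LexEntry]) -> list[Paradigm]:
    sg = [e for e in entries if e.number is Number.SG]
    pl = [e for e in entries if e.number is Number.PL]

    if len(sg) == 1 and len(pl) == 1 and sg[0].gender is not pl[0].gender:
        # Gender-changing plural (uovo M.SG / uova F.PL): couple across
        # genders, keyed by the gender of the singular.  Identical forms
        # are plain invariance and take priority.
        return [_noun_paradigm(lemma, sg[0].gender, entries)]

    if (len(sg) == 1 and len(pl) == 2
            and len({e.form for e in pl}) == 2
            and len({extract_ending(e.form).value for e in pl}) == 2
            and len({e.gender for e in pl}) == 2):
        # Over-abundant plural with a gender split (braccio M.SG,
        # braccia F.PL, bracci M.PL): one three-entry paradigm.
        return [_noun_paradigm(lemma, sg[0].gender, entries)]

    by_gender: dict[Gender, list[LexEntry]] = {}
    for e in entries:
        by_gender.setdefault(e.gender, []).append(e)
    return [
        _noun_paradigm(lemma, g, group)
        for g, group in sorted(by_gender.items(), key=lambda kv: kv[0].value)
    ]


def _build_adjective_paradigm(lemma: str, entries: list[LexEntry]) -> Paradigm:
    cells: dict[FeatureCombo, tuple[str, Ending]] = {}
    # Positive-grade forms define the paradigm cells; graded forms stay
    # attached as entries.  Within a cell the most frequent form wins.
    ranked = sorted(
        entries,
        key=lambda e: (e.grade is Grade.SUPERLATIVE, -e.token_freq, e.form),
    )
    overabundant = False
    for e in ranked:
        combo = e.combo
        if combo in cells:
            if cells[combo][0] != e.form:
                overabundant = True
            continue
        cells[combo] = (e.form, extract_ending(e.form))
    p = Paradigm(lemma=lemma, pos=Pos.ADJECTIVE, gender_key=None,
                 adj_cells=cells, entries=list(entries))
    if overabundant:
        p.flags.add("OverAbundant")
    forms = {f for f, _ in cells.values()}
    numbers = {c.number for c in cells}
    if len(forms) == 1 and numbers == {Number.SG, Number.PL}:
        p.flags.add("Inv")
    if len(cells) < 4:
        p.flags.add("NA")
    return p


def build_paradigms(lexicon: Lexicon) -> list[Paradigm]:
    """Group lexicon entries into per-lemma paradigms.

    Nouns are grouped by (lemma, gender) — homographic lemma pairs of
    different gender (musicista M/F) form separate two-cell paradigms —
    except for gender-changing and over-abundant plurals, which couple
    across genders under the singular's gender.  Adjectives are grouped
    by lemma into a four-cell paradigm.
    """
    groups: dict[tuple[str, str], list[LexEntry]] = {}
    for e in lexicon:
        groups.setdefault((e.pos.value, e.lemma), []).append(e)

    paradigms: list[Paradigm] = []
    for (pos_value, lemma), entries in sorted(groups.items()):
        if pos_value == Pos.NOUN.value:
            paradigms.extend(_build_noun_paradigms(lemma, entries))
        else:
            paradigms.append(_build_adjective_paradigm(lemma, entries))
    return paradigms


def assign_noun_class(paradigm: Paradigm) -> str:
    """Label a noun paradigm by the endings of its SG and PL cells."""
    if paradigm.pos is not Pos.NOUN:
        raise ValueError("assign_noun_class expects a noun paradigm")
    if paradigm.is_invariant:
        paradigm.class_label = "Inv"
        return paradigm.class_label

    sg = [end.value for _, end in paradigm.noun_cells.get(Number.SG, [])]
    pl = [end.value for _, end in paradigm.noun_cells.get(Number.PL, [])]

    if sg and not pl:
        label = f"{sg[0]}_NA" if len(set(sg)) == 1 else "Other"
    elif pl and not sg:
        label = f"NA_{pl[0]}" if len(set(pl)) == 1 else "Other"
    elif len(set(sg)) == 1 and len(set(pl)) == 1:
        label = NOUN_CANONICAL_CLASSES.get((sg[0], pl[0]), "Other")
    elif len(set(sg)) == 1 and sg[0] == "o" and set(pl) == {"a", "i"}:
        label = "o_a_i"
    else:
        label = "Other"
    paradigm.class_label = label
    return label


def _adjective_pair(paradigm: Paradigm, gender: Gender) -> str:
    sg = paradigm.adj_cells.get(FeatureCombo(gender, Number.SG))
    pl = paradigm.adj_cells.get(FeatureCombo(gender, Number.PL))
    if sg is None and pl is None:
        return "NA"
    sg_e = sg[1].value if sg else "NA"
    pl_e = pl[1].value if pl else "NA"
    return f"{sg_e}_{pl_e}"


def assign_adjective_class(paradigm: Paradigm) -> str:
    """Label an adjective paradigm as '<F.SG_F.PL> <M.SG_M.PL>'."""
    if paradigm.pos is not Pos.ADJECTIVE:
        raise ValueError("assign_adjective_class expects an adjective paradigm")
    if paradigm.is_invariant:
        paradigm.class_label = "Inv"
        return paradigm.class_label
    label = (f"{_adjective_pair(paradigm, Gender.F)} "
             f"{_adjective_pair(paradigm, Gender.M)}")
    paradigm.class_label = label
    return label


def label_paradigms(paradigms: Iterable[Paradigm]) -> list[Paradigm]:
    """Assign a class label to every paradigm (in place); returns the list."""
    out = list(paradigms)
    for p in out:
        if p.pos is Pos.NOUN:
            assign_noun_class(p)
        else:
            assign_adjective_class(p)
    return out


def build_labeled_paradigms(lexicon: Lexicon) -> list[Paradigm]:
    """Convenience: build_paradigms followed by class assignment."""
    return label_paradigms(build_paradigms(lexicon))


def parse_class_label(pos: Pos, label: str):
    """Parse a class label into its structural description.

    Returns a (kind, payload) pair:

    * nouns — ``("inv", None)``, ``("other", None)``,
      ``("pair", (sg, pl))``, ``("overabundant", (sg, (pl1, pl2)))`` or
      ``("one_cell", (sg_or_None, pl_or_None))``;
    * adjectives — ``("inv", None)`` or
      ``("cells", (f_sg, f_pl, m_sg, m_pl))`` with ``None`` marking an
      unattested (NA) cell.

    Raises ``ValueError`` on labels outside the grammar.
    """
    label = label.strip()
    if pos is Pos.NOUN:
        if label == "Inv":
            return ("inv", None)
        if label == "Other":
            return ("other", None)
        parts = label.split("_")
        if len(parts) == 2:
            sg, pl = parts
            if sg == "NA" and pl != "NA" and len(pl) == 1:
                return ("one_cell", (None, pl))
            if pl == "NA" and sg != "NA" and len(sg) == 1:
                return ("one_cell", (sg, None))
            if len(sg) == 1 and len(pl) == 1:
                return ("pair", (sg, pl))
        if len(parts) == 3 and all(len(x) == 1 for x in parts):
            return ("overabundant", (parts[0], (parts[1], parts[2])))
        raise ValueError(f"unparseable noun class label {label!r}")

    if label == "Inv":
        return ("inv", None)
    tokens = label.split()
    if len(tokens) != 2:
        raise ValueError(f"unparseable adjective class label {label!r}")
    cells: list[Optional[str]] = []
    for token in tokens:
        if token == "NA":
            cells.extend([None, None])
            continue
        parts = token.split("_")
        if len(parts) != 2 or not all(p == "NA" or len(p) == 1 for p in parts):
            raise ValueError(f"unparseable adjective class label {label!r}")
        cells.extend([None if p == "NA" else p for p in parts])
    return ("cells", tuple(cells))
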