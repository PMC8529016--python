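"""Seeded synthetic lexica with the structure the analysis assumes.

The generator emulates what a web-corpus frequency list merged with a
morphological annotation looks like for Italian nouns and adjectives:

* lemmas drawn from declensional classes (noun classes o_i, a_e, e_i,
  a_i, o_a, o_a_i, Inv, Other; adjective classes like "a_e o_i" and
  "e_i e_i", including defective NA classes);
* per-class gender mixtures (a noun lemma's gender is lexical;
  adjective forms cover all four gender x number cells);
* defective paradigms through per-cell dropout;
* within-POS homographs planted by making forms from compatible
  classes coincide (an e_i masculine singular with an a_e feminine
  plural, or dual-gender invariants attested in all four cells);
* heavy-tailed token frequencies following a Zipf rank-frequency law
  over all forms jointly.

Stems are CV-alternating strings ending in a consonant, so the
appended vowel is always the inflectional ending and never stem
material.  Everything is driven by one integer seed; a fixed
configuration reproduces the lexicon exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ambiguity import AmbiguityRecord
from .paradigm_builder import parse_class_label
from .types import FeatureCombo, Gender, LexEntry, Lexicon, Number, Pos

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_lexicon",
    "plant_ambiguity_report",
    "default_config",
    "config_from_dict",
]

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
#: Endings given to invariant lemmas ('' keeps the consonant-final stem).
_INV_ENDINGS = ("", "u", "è", "ò")


@dataclass(frozen=True)
class ClassSpec:
    """How many lemmas to draw from one declensional class.

    ``p_masculine`` is the probability that a noun lemma is masculine
    (ignored for adjectives, whose paradigms span both genders);
    ``cell_dropout`` is the chance that each individual cell goes
    unattested, yielding defective paradigms.
    """

    pos: Pos
    class_label: str
    n_lemmas: int
    p_masculine: float = 0.5
    cell_dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lemmas < 0:
            raise ValueError("n_lemmas must be >= 0")
        if not 0.0 <= self.p_masculine <= 1.0:
            raise ValueError("p_masculine must be in [0, 1]")
        if not 0.0 <= self.cell_dropout <= 1.0:
            raise ValueError("cell_dropout must be in [0, 1]")
        parse_class_label(self.pos, self.class_label)   # fatal if malformed


@dataclass(frozen=True)
class GeneratorConfig:
    classes: tuple[ClassSpec, ...]
    zipf_exponent: float = 1.0
    freq_scale: int = 10_000_000
    ambiguity_rate: float = 0.0
    corpus_size: int = 1_900_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if not any(c.n_lemmas > 0 for c in self.classes):
            raise ValueError("need at least one ClassSpec with n_lemmas > 0")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.freq_scale <= 0 or self.corpus_size <= 0:
            raise ValueError("freq_scale and corpus_size must be positive")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")


@dataclass
class _Cell:
    """One planned paradigm cell before frequency assignment."""

    form: str
    lemma: str
    pos: Pos
    gender: Gender
    number: Number
    protected: bool = False      # planted cells survive dropout
    dropout: float = 0.0


@dataclass
class GroundTruth:
    """Generator bookkeeping: true classes and planted homographs."""

    lemma_classes: pd.DataFrame     # pos, lemma, gender_key, class_label
    planted: list[tuple[str, str, str]] = field(default_factory=list)
    #         (form, pos value, pattern)
    attested: list[_Cell] = field(default_factory=list)


def _new_stem(rng: np.random.Generator, used: set[str]) -> str:
    """Unique CV-alternating stem, consonant-final, length >= 3."""
    while True:
        n_syll = int(rng.integers(1, 4))          # CVC, CVCVC, CVCVCVC
        chars = []
        for _ in range(n_syll):
            chars.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
            chars.append(_VOWELS[rng.integers(len(_VOWELS))])
        chars.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        stem = "".join(chars)
        if stem not in used:
            used.add(stem)
            return stem


def _draw_gender(rng: np.random.Generator, p_masculine: float) -> Gender:
    return Gender.M if rng.random() < p_masculine else Gender.F


def _flip(g: Gender) -> Gender:
    return Gender.F if g is Gender.M else Gender.M


def _noun_cells(stem: str, kind: str, payload, gender: Gender,
                rng: np.random.Generator,
                dropout: float) -> tuple[str, Gender, list[_Cell]]:
    """Plan the cells of one noun lemma; returns (lemma, gender_key, cells)."""
    if kind == "pair":
        sg_e, pl_e = payload
        lemma = stem + sg_e
        pl_gender = _flip(gender) if (sg_e, pl_e) == ("o", "a") else gender
        cells = [
            _Cell(stem + sg_e, lemma, Pos.NOUN, gender, Number.SG, dropout=dropout),
            _Cell(stem + pl_e, lemma, Pos.NOUN, pl_gender, Number.PL, dropout=dropout),
        ]
    elif kind == "overabundant":
        sg_e, (pl1, pl2) = payload
        lemma = stem + sg_e
        cells = [
            _Cell(stem + sg_e, lemma, Pos.NOUN, gender, Number.SG, dropout=dropout),
            _Cell(stem + pl1, lemma, Pos.NOUN, _flip(gender), Number.PL, dropout=dropout),
            _Cell(stem + pl2, lemma, Pos.NOUN, gender, Number.PL, dropout=dropout),
        ]
    elif kind == "inv":
        form = stem + _INV_ENDINGS[rng.integers(len(_INV_ENDINGS))]
        lemma = form
        cells = [
            _Cell(form, lemma, Pos.NOUN, gender, Number.SG, dropout=dropout),
            _Cell(form, lemma, Pos.NOUN, gender, Number.PL, dropout=dropout),
        ]
    elif kind == "other":
        lemma = stem
        cells = [
            _Cell(stem, lemma, Pos.NOUN, gender, Number.SG, dropout=dropout),
            _Cell(stem + "s", lemma, Pos.NOUN, gender, Number.PL, dropout=dropout),
        ]
    elif kind == "one_cell":
        sg_e, pl_e = payload
        if sg_e is not None:
            lemma = stem + sg_e
            cells = [_Cell(lemma, lemma, Pos.NOUN, gender, Number.SG,
                           dropout=dropout)]
        else:
            lemma = stem + pl_e
            cells = [_Cell(lemma, lemma, Pos.NOUN, gender, Number.PL,
                           dropout=dropout)]
    else:                                         # pragma: no cover
        raise ValueError(f"unknown noun label kind {kind!r}")
    return lemma, gender, cells


def _adjective_cells(stem: str, kind: str, payload,
                     rng: np.random.Generator,
                     dropout: float) -> tuple[str, list[_Cell]]:
    if kind == "inv":
        form = stem + _INV_ENDINGS[rng.integers(len(_INV_ENDINGS))]
        lemma = form
        cells = [
            _Cell(form, lemma, Pos.ADJECTIVE, g, n, dropout=dropout)
            for g in (Gender.F, Gender.M) for n in (Number.SG, Number.PL)
        ]
        return lemma, cells
    f_sg, f_pl, m_sg, m_pl = payload
    lemma = stem + (m_sg or f_sg or m_pl or f_pl)
    plan = [
        (f_sg, Gender.F, Number.SG),
        (f_pl, Gender.F, Number.PL),
        (m_sg, Gender.M, Number.SG),
        (m_pl, Gender.M, Number.PL),
    ]
    cells = [
        _Cell(stem + e, lemma, Pos.ADJECTIVE, g, n, dropout=dropout)
        for e, g, n in plan if e is not None
    ]
    return lemma, cells


def _plan_plants(config: GeneratorConfig, lemma_plans: list[dict],
                 n_forms: int) -> tuple[list, list]:
    """Pick which lemmas get rewritten into planted homographs.

    Supported patterns: class-intersection pairs (an e_i masculine
    singular coinciding with an a_e feminine plural), and dual-gender
    invariant nouns attested in all four combinations.  Each plant
    creates exactly one ambiguous form.
    """
    target = int(round(config.ambiguity_rate * n_forms))
    if target == 0:
        return [], []

    ei = [p for p in lemma_plans
          if p["pos"] is Pos.NOUN and p["label"] == "e_i"]
    ae = [p for p in lemma_plans
          if p["pos"] is Pos.NOUN and p["label"] == "a_e"]
    inv = [p for p in lemma_plans
           if p["pos"] is Pos.NOUN and p["label"] == "Inv"]

    n_cam = min(target, len(ei), len(ae))
    cam_pairs = list(zip(ei[:n_cam], ae[:n_cam]))
    n_four = min(target - n_cam, len(inv))
    four = inv[:n_four]
    if n_cam + n_four < target:
        warnings.warn(
            f"requested {target} planted homographs but only "
            f"{n_cam + n_four} are possible under the configured classes; "
            "rate reduced",
            stacklevel=3,
        )
    return cam_pairs, four


def generate_lexicon(config: GeneratorConfig) -> tuple[Lexicon, GroundTruth]:
    """Draw a seeded lexicon plus its ground truth.

    Returns ``(lexicon, truth)`` where ``truth`` carries the true
    class label of every lemma, the planted homographs, and the full
    list of attested cells (the oracle for ambiguity detection).
    """
    rng = np.random.default_rng(config.seed)
    used_stems: set[str] = set()

    # Pass 1: plan one record per lemma (stem, gender, parsed label).
    lemma_plans: list[dict] = []
    for spec in config.classes:
        kind, payload = parse_class_label(spec.pos, spec.class_label)
        for _ in range(spec.n_lemmas):
            plan = {
                "pos": spec.pos,
                "label": spec.class_label,
                "kind": kind,
                "payload": payload,
                "stem": _new_stem(rng, used_stems),
                "gender": _draw_gender(rng, spec.p_masculine),
                "dropout": spec.cell_dropout,
                "plant": None,
            }
            lemma_plans.append(plan)

    # Count planned distinct forms to size the planting target.
    n_forms_est = 0
    for p in lemma_plans:
        if p["kind"] in ("pair", "other"):
            n_forms_est += 2
        elif p["kind"] == "overabundant":
            n_forms_est += 3
        elif p["kind"] in ("inv", "one_cell"):
            n_forms_est += 1
        else:
            n_forms_est += len([e for e in p["payload"] if e is not None])

    cam_pairs, four_way = _plan_plants(config, lemma_plans, n_forms_est)
    for ei_plan, ae_plan in cam_pairs:
        shared = _new_stem(rng, used_stems)
        ei_plan.update(stem=shared, gender=Gender.M, plant="cameriere")
        ae_plan.update(stem=shared, gender=Gender.F, plant="cameriere")
    for plan in four_way:
        plan["plant"] = "fourway"

    # Pass 2: realize cells.
    planted: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    cells: list[_Cell] = []
    for p in lemma_plans:
        if p["pos"] is Pos.NOUN:
            lemma, gkey, lemma_cells = _noun_cells(
                p["stem"], p["kind"], p["payload"], p["gender"], rng,
                p["dropout"],
            )
            if p["plant"] == "cameriere":
                # Protect the shared form's cell: M.SG of e_i / F.PL of a_e.
                for c in lemma_cells:
                    if c.form.endswith("e"):
                        c.protected = True
                if p["label"] == "e_i":
                    planted.append((p["stem"] + "e", Pos.NOUN.value,
                                    "F.PL-M.SG"))
            elif p["plant"] == "fourway":
                both = []
                for g in (Gender.F, Gender.M):
                    for c in lemma_cells:
                        both.append(replace_cell(c, gender=g, protected=True))
                lemma_cells = both
                planted.append((lemma_cells[0].form, Pos.NOUN.value,
                                "F.PL-F.SG-M.PL-M.SG"))
                truth_rows.append({"pos": Pos.NOUN.value, "lemma": lemma,
                                   "gender_key": _flip(gkey).value,
                                   "class_label": p["label"]})
            truth_rows.append({"pos": Pos.NOUN.value, "lemma": lemma,
                               "gender_key": gkey.value,
                               "class_label": p["label"]})
        else:
            lemma, lemma_cells = _adjective_cells(
                p["stem"], p["kind"], p["payload"], rng, p["dropout"]
            )
            truth_rows.append({"pos": Pos.ADJECTIVE.value, "lemma": lemma,
                               "gender_key": "",
                               "class_label": p["label"]})
        cells.extend(lemma_cells)

    # Dropout (planted cells are immune), then dedup on the entry key.
    attested: list[_Cell] = []
    seen_keys: set[tuple] = set()
    for c in cells:
        if not c.protected and c.dropout > 0 and rng.random() < c.dropout:
            continue
        key = (c.form, c.pos.value, c.gender.value, c.number.value, c.lemma)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        attested.append(c)

    # Zipf frequencies over all distinct (form, pos) jointly.
    form_keys = sorted({(c.form, c.pos.value) for c in attested})
    order = rng.permutation(len(form_keys))
    freq_of: dict[tuple[str, str], int] = {}
    for rank0, idx in enumerate(order):
        freq = max(1, int(round(
            config.freq_scale * (rank0 + 1) ** (-config.zipf_exponent)
        )))
        freq_of[form_keys[idx]] = freq

    entries = [
        LexEntry(form=c.form, lemma=c.lemma, pos=c.pos, gender=c.gender,
                 number=c.number, token_freq=freq_of[(c.form, c.pos.value)])
        for c in attested
    ]
    lexicon = Lexicon(entries, corpus_size=config.corpus_size)
    truth = GroundTruth(
        lemma_classes=pd.DataFrame(
            truth_rows, columns=["pos", "lemma", "gender_key", "class_label"]
        ),
        planted=planted,
        attested=attested,
    )
    return lexicon, truth


def replace_cell(c: _Cell, **kw) -> _Cell:
    d = dict(form=c.form, lemma=c.lemma, pos=c.pos, gender=c.gender,
             number=c.number, protected=c.protected, dropout=c.dropout)
    d.update(kw)
    return _Cell(**d)


def plant_ambiguity_report(lexicon: Lexicon,
                           truth: GroundTruth) -> set[AmbiguityRecord]:
    """The exact ambiguity set the detector must find.

    Derived from the generator's own attestation bookkeeping (every
    cell it emitted), not from the lexicon, so it is an independent
    oracle for the detection stage.  Covers both planted homographs
    and the structural ones (invariant lemmas spanning singular and
    plural, gender-syncretic adjective cells).
    """
    by_form: dict[tuple[str, Pos], list[_Cell]] = {}
    for c in truth.attested:
        by_form.setdefault((c.form, c.pos), []).append(c)

    expected: set[AmbiguityRecord] = set()
    for (form, pos), group in by_form.items():
        combos = frozenset(FeatureCombo(c.gender, c.number) for c in group)
        if len(combos) >= 2:
            expected.add(
                AmbiguityRecord(
                    form=form, pos=pos, combos=combos,
                    member_lemmas=frozenset(c.lemma for c in group),
                )
            )
    return expected


def default_config(seed: int = 0, scale: float = 0.1,
                   ambiguity_rate: float = 0.005) -> GeneratorConfig:
    """The standard study conditions, at a configurable size.

    Class inventories and per-class gender mixtures mirror the
    published distribution of Italian noun and adjective lemmas over
    declensional classes; ``scale`` multiplies every lemma count
    (0.1 keeps the full pipeline comfortably fast while leaving
    hundreds of lemmas in the major classes).  Token frequencies
    follow a Zipf law with exponent 1, the classic regime of word
    frequency lists; the rank-1 frequency (1e7) and corpus size
    (1.9e9) match a large web corpus.
    """
    def n(x: int) -> int:
        return max(1, int(round(x * scale)))

    noun = [
        # label, full-scale lemma count, share of masculine lemmas
        ("o_i", 11959, 11957 / 11959),
        ("a_e", 8318, 0.0),
        ("e_i", 7175, 3907 / 7175),
        ("a_i", 936, 932 / 936),
        ("o_a", 46, 0.5),
        ("o_a_i", 56, 42 / 56),
        ("Inv", 42, 40 / 42),
        ("Other", 144, 89 / 144),
    ]
    adjective = [
        # label, full-scale lemma count (max attested cell count)
        ("a_e o_i", 6137, 0.05),
        ("e_i e_i", 148, 0.0),
        ("NA o_i", 287, 0.0),
        ("a_NA NA", 458, 0.0),
        ("NA o_NA", 395, 0.0),
        ("a_e NA", 131, 0.0),
        ("NA_e NA", 242, 0.0),
        ("NA NA_i", 240, 0.0),
        ("NA e_i", 19, 0.0),
        ("e_NA NA", 11, 0.0),
    ]
    classes = [
        ClassSpec(Pos.NOUN, label, n(count), p_masculine=p_m,
                  cell_dropout=0.03)
        for label, count, p_m in noun
    ] + [
        ClassSpec(Pos.ADJECTIVE, label, n(count), cell_dropout=dropout)
        for label, count, dropout in adjective
    ]
    return GeneratorConfig(classes=tuple(classes), zipf_exponent=1.0,
                           freq_scale=10_000_000,
                           ambiguity_rate=ambiguity_rate,
                           corpus_size=1_900_000_000, seed=seed)


def config_from_dict(data: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a parsed YAML/JSON mapping."""
    classes = tuple(
        ClassSpec(
            pos=Pos(c["pos"]),
            class_label=c["class_label"],
            n_lemmas=int(c["n_lemmas"]),
            p_masculine=float(c.get("p_masculine", 0.5)),
            cell_dropout=float(c.get("cell_dropout", 0.0)),
        )
        for c in data["classes"]
    )
    return GeneratorConfig(
        classes=classes,
        zipf_exponent=float(data.get("zipf_exponent", 1.0)),
        freq_scale=int(data.get("freq_scale", 10_000_000)),
        ambiguity_rate=float(data.get("ambiguity_rate", 0.0)),
        corpus_size=int(data.get("corpus_size", 1_900_000_000)),
        seed=int(data.get("seed", 0)),
    )
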