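"""Read, validate, merge, and write annotated word-form frequency lexica.

The on-disk format is UTF-8 tab-separated text with a header row.  A
*dialect* maps the semantic fields (form, lemma, pos, gender, number,
frequency, grade) to the column names actually present in a file, so
Morph-it!-style exports and generic TSVs can be read without code
changes.  Frequencies are raw corpus token counts; per-million
standardization is derived from the corpus size at write time.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .types import (
    Gender,
    Grade,
    LexEntry,
    Lexicon,
    Number,
    Pos,
    normalize_form,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DIALECTS",
    "LexiconFormatError",
    "MergeError",
    "ReadReport",
    "MergeReport",
    "read_lexicon",
    "merge_frequency_annotation",
    "standardize_frequency",
    "write_flexit_table",
]


class LexiconFormatError(ValueError):
    """Fatal problem with an input table (missing column, bad dialect...)."""


class MergeError(ValueError):
    """Fatal problem while joining frequencies with annotations."""


#: Built-in dialect maps: semantic field -> column name.
DIALECTS: dict[str, dict[str, str]] = {
    # The format written by write_flexit_table (and read back round-trip).
    "flexit": {
        "form": "form",
        "lemma": "lemma",
        "pos": "pos",
        "gender": "gender",
        "number": "number",
        "frequency": "raw_freq",
        "grade": "grade",
    },
    # Plain TSV with self-describing column names.
    "generic": {
        "form": "form",
        "lemma": "lemma",
        "pos": "pos",
        "gender": "gender",
        "number": "number",
        "frequency": "frequency",
        "grade": "grade",
    },
}

_REQUIRED_FIELDS = ("form", "lemma", "pos", "gender", "number", "frequency")

_POS_CODES = {
    "noun": Pos.NOUN,
    "n": Pos.NOUN,
    "adjective": Pos.ADJECTIVE,
    "adj": Pos.ADJECTIVE,
}
_GENDER_CODES = {"f": Gender.F, "m": Gender.M}
_NUMBER_CODES = {"sg": Number.SG, "pl": Number.PL}
_GRADE_CODES = {
    "": None,
    "positive": Grade.POSITIVE,
    "pos": Grade.POSITIVE,
    "superlative": Grade.SUPERLATIVE,
    "sup": Grade.SUPERLATIVE,
}


@dataclass
class ReadReport:
    """Row-level outcome of parsing one lexicon file."""

    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_merged_duplicates: int = 0
    reasons: Counter = field(default_factory=Counter)
    rejected_lines: list[tuple[int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected_lines, columns=["line", "reason"])


@dataclass
class MergeReport:
    """Join diagnostics of merge_frequency_annotation."""

    n_matched: int = 0
    unmatched_frequency: list[tuple[str, str]] = field(default_factory=list)
    unmatched_annotation: list[tuple[str, str]] = field(default_factory=list)


def _decode_row(row: Mapping[str, object], line_no: int, report: ReadReport):
    """Decode one raw TSV row into LexEntry fields; None on rejection."""

    def _reject(reason: str):
        report.n_rejected += 1
        report.reasons[reason] += 1
        report.rejected_lines.append((line_no, reason))
        return None

    form = normalize_form(str(row["form"]) if pd.notna(row["form"]) else "")
    if not form:
        return _reject("empty form")
    lemma = normalize_form(str(row["lemma"]) if pd.notna(row["lemma"]) else "")
    if not lemma:
        return _reject("empty lemma")

    pos_raw = str(row["pos"]).strip().casefold() if pd.notna(row["pos"]) else ""
    if pos_raw not in _POS_CODES:
        return _reject(f"unknown pos code {pos_raw!r}")
    gender_raw = str(row["gender"]).strip().casefold() if pd.notna(row["gender"]) else ""
    if gender_raw not in _GENDER_CODES:
        return _reject(f"unknown gender code {gender_raw!r}")
    number_raw = str(row["number"]).strip().casefold() if pd.notna(row["number"]) else ""
    if number_raw not in _NUMBER_CODES:
        return _reject(f"unknown number code {number_raw!r}")

    freq_raw = row["frequency"]
    try:
        freq_float = float(freq_raw)
        freq = int(freq_float)
        if freq != freq_float or freq < 0:
            raise ValueError
    except (TypeError, ValueError):
        return _reject(f"malformed frequency {freq_raw!r} at line {line_no}")

    grade_raw = ""
    if "grade" in row and pd.notna(row["grade"]):
        grade_raw = str(row["grade"]).strip().casefold()
    if grade_raw not in _GRADE_CODES:
        return _reject(f"unknown grade code {grade_raw!r}")

    return (
        form,
        lemma,
        _POS_CODES[pos_raw],
        _GENDER_CODES[gender_raw],
        _NUMBER_CODES[number_raw],
        freq,
        _GRADE_CODES[grade_raw],
    )


def _assemble(decoded: Iterable[tuple], report: ReadReport) -> list[LexEntry]:
    """Build entries, summing frequencies of duplicate-key rows."""
    merged: dict[tuple, list] = {}
    order: list[tuple] = []
    for form, lemma, pos, gender, number, freq, grade in decoded:
        key = (form, pos, gender, number, lemma)
        if key in merged:
            merged[key][0] += freq
            if merged[key][1] is None:
                merged[key][1] = grade
            report.n_merged_duplicates += 1
            logger.warning(
                "duplicate row for %s/%s %s.%s of lemma %s: frequencies summed",
                form, pos.value, gender.value, number.value, lemma,
            )
        else:
            merged[key] = [freq, grade]
            order.append(key)
    entries = []
    for key in order:
        form, pos, gender, number, lemma = key
        freq, grade = merged[key]
        entries.append(
            LexEntry(form=form, lemma=lemma, pos=pos, gender=gender,
                     number=number, token_freq=freq, grade=grade)
        )
    return entries


def read_lexicon(
    path: Union[str, Path],
    dialect: str = "flexit",
    corpus_size: int = 1,
    *,
    dialect_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
    max_reject_fraction: float = 0.5,
    return_report: bool = False,
):
    """Parse a TSV lexicon file into a validated :class:`Lexicon`.

    Rows with unknown pos/gender/number codes or malformed frequencies
    are rejected and tallied in a :class:`ReadReport`; duplicate
    (form, pos, gender, number, lemma) rows have their frequencies
    summed with a logged warning.  If more than ``max_reject_fraction``
    of the rows are rejected the file is assumed to be in the wrong
    dialect and the whole read fails.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        Name of the column map to use (see :data:`DIALECTS`).
    corpus_size:
        Token size of the source corpus, attached to the Lexicon for
        per-million standardization.
    dialect_maps:
        Extra dialect maps (e.g. from a config file); they shadow the
        built-ins on name collision.
    return_report:
        If true, return ``(lexicon, report)`` instead of the lexicon.
    """
    maps = dict(DIALECTS)
    if dialect_maps:
        maps.update({k: dict(v) for k, v in dialect_maps.items()})
    if dialect not in maps:
        raise LexiconFormatError(
            f"unknown dialect {dialect!r}; known: {sorted(maps)}"
        )
    colmap = maps[dialect]

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      na_values=[], encoding="utf-8")

    for semantic in _REQUIRED_FIELDS:
        col = colmap.get(semantic, semantic)
        if col not in raw.columns:
            raise LexiconFormatError(
                f"required column {col!r} (field {semantic!r}) missing "
                f"from {path.name}; found {list(raw.columns)}"
            )

    rename = {colmap.get(k, k): k for k in colmap}
    table = raw.rename(columns=rename)
    has_grade = "grade" in table.columns

    report = ReadReport(n_rows=len(table))
    decoded = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        d = row._asdict()
        if not has_grade:
            d["grade"] = ""
        fields = _decode_row(d, i, report)
        if fields is not None:
            decoded.append(fields)
    report.n_accepted = len(decoded)

    if report.n_rows and report.n_rejected / report.n_rows > max_reject_fraction:
        raise LexiconFormatError(
            f"{report.n_rejected}/{report.n_rows} rows rejected while reading "
            f"{path.name} with dialect {dialect!r}; likely a dialect mismatch. "
            f"Top reasons: {report.reasons.most_common(3)}"
        )
    if report.n_rejected:
        logger.warning("rejected %d/%d rows reading %s: %s",
                       report.n_rejected, report.n_rows, path.name,
                       report.reasons.most_common(5))

    entries = _assemble(decoded, report)
    lexicon = Lexicon(entries, corpus_size=corpus_size, dialect=dialect)
    if return_report:
        return lexicon, report
    return lexicon


def merge_frequency_annotation(
    freq_table: pd.DataFrame,
    annotation: pd.DataFrame,
    corpus_size: int = 1,
    *,
    return_report: bool = False,
):
    """Join a (form, pos, token_freq) table with a morphological annotation.

    Corpus frequency lists are tagged at the part-of-speech level only,
    so a form annotated with k > 1 feature-value combinations within one
    POS yields k entries that all carry the SAME undivided token
    frequency — the within-POS homography that the ambiguity stage
    detects and the token counting policy later excludes.

    ``freq_table`` needs columns form/pos/token_freq with one row per
    (form, pos); ``annotation`` needs form/pos/lemma/gender/number and
    optionally grade.  Unmatched rows on either side are reported, not
    fatal; an empty join is fatal.
    """
    for col in ("form", "pos", "token_freq"):
        if col not in freq_table.columns:
            raise MergeError(f"frequency table lacks column {col!r}")
    for col in ("form", "pos", "lemma", "gender", "number"):
        if col not in annotation.columns:
            raise MergeError(f"annotation table lacks column {col!r}")

    freq = freq_table.copy()
    freq["form"] = freq["form"].map(lambda s: normalize_form(str(s)))
    freq["pos"] = freq["pos"].map(lambda s: str(s).strip().casefold())
    if freq.duplicated(subset=["form", "pos"]).any():
        dup = freq[freq.duplicated(subset=["form", "pos"], keep=False)]
        raise MergeError(
            f"duplicate (form, pos) keys in frequency table: "
            f"{sorted(set(map(tuple, dup[['form', 'pos']].values)))[:5]}"
        )

    annot = annotation.copy()
    annot["form"] = annot["form"].map(lambda s: normalize_form(str(s)))
    annot["pos"] = annot["pos"].map(lambda s: str(s).strip().casefold())
    if "grade" not in annot.columns:
        annot["grade"] = ""

    freq_keys = set(map(tuple, freq[["form", "pos"]].values))
    annot_keys = set(map(tuple, annot[["form", "pos"]].values))

    report = MergeReport(
        unmatched_frequency=sorted(freq_keys - annot_keys),
        unmatched_annotation=sorted(annot_keys - freq_keys),
    )

    joined = annot.merge(freq[["form", "pos", "token_freq"]],
                         on=["form", "pos"], how="inner")
    if joined.empty:
        raise MergeError(
            f"empty join: {len(freq)} frequency rows, {len(annot)} annotation "
            f"rows, 0 matches ({len(report.unmatched_frequency)} frequency "
            f"keys unmatched, {len(report.unmatched_annotation)} annotation "
            "keys unmatched)"
        )
    report.n_matched = len(joined)
    if report.unmatched_frequency:
        logger.warning("%d frequency keys had no annotation",
                       len(report.unmatched_frequency))
    if report.unmatched_annotation:
        logger.warning("%d annotation keys had no frequency",
                       len(report.unmatched_annotation))

    read_rep = ReadReport(n_rows=len(joined))
    decoded = []
    for i, row in enumerate(joined.itertuples(index=False), start=1):
        d = row._asdict()
        d["frequency"] = d.pop("token_freq")
        fields = _decode_row(d, i, read_rep)
        if fields is not None:
            decoded.append(fields)
    entries = _assemble(decoded, read_rep)
    lexicon = Lexicon(entries, corpus_size=corpus_size)
    if return_report:
        return lexicon, report
    return lexicon


def standardize_frequency(entry_or_count: Union[LexEntry, int],
                          corpus_size: int) -> float:
    """Occurrences per million corpus tokens: freq * 1e6 / corpus_size."""
    if corpus_size <= 0:
        raise LexiconFormatError(
            f"corpus_size must be positive for standardization, got {corpus_size}"
        )
    freq = (entry_or_count.token_freq
            if isinstance(entry_or_count, LexEntry) else int(entry_or_count))
    return freq * 1_000_000 / corpus_size


def write_flexit_table(lexicon: Lexicon, paradigms, path: Union[str, Path]) -> None:
    """Write the full annotated table: forms, endings, classes, frequencies.

    ``paradigms`` is an iterable of labelled :class:`~flexent.paradigm_builder.Paradigm`
    objects covering every entry of the lexicon; each output row carries
    the declensional-class label of the paradigm its entry belongs to.
    Row order is deterministic (pos, lemma, gender, number, form) and the
    output re-reads into an equal lexicon under the ``flexit`` dialect.
    """
    from .paradigm_builder import extract_ending

    label_by_key: dict[tuple, str] = {}
    for p in paradigms:
        if p.class_label is None:
            raise LexiconFormatError(
                f"paradigm of lemma {p.lemma!r} has no class label; "
                "run the class assignment first"
            )
        for e in p.entries:
            label_by_key[e.key] = p.class_label

    rows = []
    for e in lexicon:
        label = label_by_key.get(e.key)
        if label is None:
            raise LexiconFormatError(
                f"no class label available for lemma {e.lemma!r} "
                f"(form {e.form!r}); paradigms do not cover the lexicon"
            )
        rows.append(
            {
                "form": e.form,
                "lemma": e.lemma,
                "pos": e.pos.value,
                "gender": e.gender.value,
                "number": e.number.value,
                "ending": extract_ending(e.form).value,
                "class": label,
                "grade": e.grade.value if e.grade else "",
                "raw_freq": e.token_freq,
                "freq_per_million": repr(
                    standardize_frequency(e, lexicon.corpus_size)
                ),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["form", "lemma", "pos", "gender", "number", "ending",
                 "class", "grade", "raw_freq", "freq_per_million"],
    )
    if len(frame):
        frame = frame.sort_values(
            ["pos", "lemma", "gender", "number", "form"], kind="mergesort"
        )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8",
                 lineterminator="\n")
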