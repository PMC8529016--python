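"""Lexicon I/O: parsing, validation, merging, standardization, round trips."""

from __future__ import annotations

import math

import pandas as pd
import pytest

from flexent.lexicon_io import (
    LexiconFormatError,
    MergeError,
    merge_frequency_annotation,
    read_lexicon,
    standardize_frequency,
    write_flexit_table,
)
from flexent.paradigm_builder import build_labeled_paradigms
from flexent.synthetic_lexicon import default_config, generate_lexicon
from flexent.types import Lexicon

from conftest import entry, N, A, F, M, SG, PL

HEADER = "form\tlemma\tpos\tgender\tnumber\tfrequency\tgrade\n"


def write_tsv(path, rows, header=HEADER):
    path.write_text(header + "".join(r + "\n" for r in rows),
                    encoding="utf-8")
    return path


class TestReadLexicon:
    def test_wellformed_rows_round_into_entries(self, tmp_path):
        p = write_tsv(tmp_path / "lex.tsv", [
            "gatto\tgatto\tnoun\tM\tSG\t100\t",
            "gatti\tgatto\tnoun\tM\tPL\t40\t",
            "rosa\trosa\tnoun\tF\tSG\t50\t",
            "bello\tbello\tadjective\tM\tSG\t60\tpositive",
        ])
        lex = read_lexicon(p, dialect="generic", corpus_size=1000)
        assert len(lex) == 4
        assert lex.corpus_size == 1000
        forms = {(e.form, e.pos.value, e.token_freq) for e in lex}
        assert ("gatto", "noun", 100) in forms
        assert ("bello", "adjective", 60) in forms

    def test_duplicate_key_rows_sum_frequencies(self, tmp_path):
        p = write_tsv(tmp_path / "dup.tsv", [
            "gatto\tgatto\tnoun\tM\tSG\t3\t",
            "gatto\tgatto\tnoun\tM\tSG\t5\t",
        ])
        lex, report = read_lexicon(p, dialect="generic", return_report=True)
        assert len(lex) == 1
        assert lex.entries[0].token_freq == 8
        assert report.n_merged_duplicates == 1

    def test_unknown_gender_code_rejects_row(self, tmp_path):
        p = write_tsv(tmp_path / "bad.tsv", [
            "gatto\tgatto\tnoun\tM\tSG\t3\t",
            "cosa\tcosa\tnoun\tN\tSG\t5\t",
            "casa\tcasa\tnoun\tF\tSG\t2\t",
        ])
        lex, report = read_lexicon(p, dialect="generic", return_report=True)
        assert len(lex) == 2
        assert report.n_rejected == 1
        assert any("gender" in r for r in report.reasons)

    def test_malformed_frequency_reports_line_number(self, tmp_path):
        p = write_tsv(tmp_path / "freq.tsv", [
            "gatto\tgatto\tnoun\tM\tSG\tmany\t",
            "casa\tcasa\tnoun\tF\tSG\t-3\t",
            "cane\tcane\tnoun\tM\tSG\t7\t",
            "cani\tcane\tnoun\tM\tPL\t3\t",
        ])
        lex, report = read_lexicon(p, dialect="generic", return_report=True)
        assert len(lex) == 2
        assert report.n_rejected == 2
        # line numbers refer to the file (header = line 1)
        assert {line for line, _ in report.rejected_lines} == {2, 3}

    def test_missing_required_column_is_fatal_and_named(self, tmp_path):
        p = write_tsv(tmp_path / "cols.tsv", ["gatto\tgatto\tnoun\tM\t3"],
                      header="form\tlemma\tpos\tgender\tfrequency\n")
        with pytest.raises(LexiconFormatError, match="number"):
            read_lexicon(p, dialect="generic")

    def test_majority_rejection_signals_dialect_mismatch(self, tmp_path):
        p = write_tsv(tmp_path / "wrong.tsv", [
            "gatto\tgatto\tVER\tX\tY\t3\t",
            "casa\tcasa\tVER\tX\tY\t5\t",
            "cane\tcane\tnoun\tM\tSG\t2\t",
        ])
        with pytest.raises(LexiconFormatError, match="dialect"):
            read_lexicon(p, dialect="generic")

    def test_forms_are_nfc_normalized_and_casefolded(self, tmp_path):
        # decomposed a + combining grave must normalize to composed \u00e0
        p = write_tsv(tmp_path / "norm.tsv", [
            "Citta\u0300\tcitta\u0300\tnoun\tF\tSG\t9\t",
        ])
        lex = read_lexicon(p, dialect="generic")
        assert lex.entries[0].form == "citt\u00e0"
        assert lex.entries[0].form[-1] == "\u00e0"

    def test_custom_dialect_map(self, tmp_path):
        p = write_tsv(tmp_path / "cust.tsv", ["gatto\tgatto\tnoun\tM\tSG\t4"],
                      header="wordform\tlemma\tpos\tgender\tnumber\tcount\n")
        lex = read_lexicon(
            p, dialect="mine",
            dialect_maps={"mine": {"form": "wordform", "lemma": "lemma",
                                   "pos": "pos", "gender": "gender",
                                   "number": "number", "frequency": "count"}},
        )
        assert len(lex) == 1 and lex.entries[0].token_freq == 4


class TestMerge:
    def test_pos_level_frequency_is_undivided_across_annotations(self):
        freq = pd.DataFrame([{"form": "cameriere", "pos": "noun",
                              "token_freq": 5232}])
        annot = pd.DataFrame([
            {"form": "cameriere", "pos": "noun", "lemma": "cameriere",
             "gender": "M", "number": "SG"},
            {"form": "cameriere", "pos": "noun", "lemma": "cameriera",
             "gender": "F", "number": "PL"},
        ])
        lex = merge_frequency_annotation(freq, annot)
        assert len(lex) == 2
        assert all(e.token_freq == 5232 for e in lex)

    def test_bijective_join_carries_each_frequency(self):
        freq = pd.DataFrame([
            {"form": f, "pos": "noun", "token_freq": tf}
            for f, tf in [("gatto", 7), ("casa", 9), ("cane", 11)]
        ])
        annot = pd.DataFrame([
            {"form": f, "pos": "noun", "lemma": f, "gender": g, "number": "SG"}
            for f, g in [("gatto", "M"), ("casa", "F"), ("cane", "M")]
        ])
        lex = merge_frequency_annotation(freq, annot)
        assert {(e.form, e.token_freq) for e in lex} == {
            ("gatto", 7), ("casa", 9), ("cane", 11)}

    def test_unmatched_frequency_rows_are_reported(self):
        freq = pd.DataFrame([
            {"form": "gatto", "pos": "noun", "token_freq": 7},
            {"form": "xyzzy", "pos": "noun", "token_freq": 3},
        ])
        annot = pd.DataFrame([{"form": "gatto", "pos": "noun",
                               "lemma": "gatto", "gender": "M",
                               "number": "SG"}])
        lex, report = merge_frequency_annotation(freq, annot,
                                                 return_report=True)
        assert len(lex) == 1
        assert report.unmatched_frequency == [("xyzzy", "noun")]

    def test_duplicate_frequency_key_is_fatal(self):
        freq = pd.DataFrame([
            {"form": "gatto", "pos": "noun", "token_freq": 7},
            {"form": "gatto", "pos": "noun", "token_freq": 8},
        ])
        annot = pd.DataFrame([{"form": "gatto", "pos": "noun",
                               "lemma": "gatto", "gender": "M",
                               "number": "SG"}])
        with pytest.raises(MergeError, match="duplicate"):
            merge_frequency_annotation(freq, annot)

    def test_empty_join_is_fatal_with_diagnostics(self):
        freq = pd.DataFrame([{"form": "gatto", "pos": "noun",
                              "token_freq": 7}])
        annot = pd.DataFrame([{"form": "casa", "pos": "noun",
                               "lemma": "casa", "gender": "F",
                               "number": "SG"}])
        with pytest.raises(MergeError, match="empty join"):
            merge_frequency_annotation(freq, annot)


class TestStandardizeFrequency:
    @pytest.mark.parametrize("freq,corpus,expected", [
        (1_900, 1_900_000_000, 1.0),
        (0, 1_900_000_000, 0.0),
        (5232, 1_900_000_000, 5232 * 1e6 / 1.9e9),   # ~2.7537e-3
    ])
    def test_per_million_values(self, freq, corpus, expected):
        assert math.isclose(standardize_frequency(freq, corpus), expected,
                            rel_tol=1e-12)

    def test_zero_corpus_size_is_fatal(self):
        with pytest.raises(LexiconFormatError):
            standardize_frequency(10, 0)


class TestWriteFlexitTable:
    def test_round_trip_preserves_projection(self, tmp_path,
                                             exemplar_lexicon):
        paradigms = build_labeled_paradigms(exemplar_lexicon)
        out = tmp_path / "flexit.tsv"
        write_flexit_table(exemplar_lexicon, paradigms, out)
        back = read_lexicon(out, dialect="flexit",
                            corpus_size=exemplar_lexicon.corpus_size)
        assert exemplar_lexicon.equals_projection(back)
        assert back.total_tokens == exemplar_lexicon.total_tokens

    def test_endings_and_classes_in_output(self, tmp_path):
        lex = Lexicon([entry("gatto", "gatto", N, M, SG, 5),
                       entry("gatti", "gatto", N, M, PL, 3)],
                      corpus_size=100)
        out = tmp_path / "gatto.tsv"
        write_flexit_table(lex, build_labeled_paradigms(lex), out)
        table = pd.read_csv(out, sep="\t")
        assert list(table["ending"]) == ["i", "o"]       # sorted PL, SG
        assert set(table["class"]) == {"o_i"}

    def test_empty_lexicon_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_flexit_table(Lexicon([], corpus_size=10), [], out)
        text = out.read_text(encoding="utf-8")
        assert text.startswith("form\tlemma\tpos")
        assert len(text.splitlines()) == 1

    def test_output_is_deterministic_bytes(self, tmp_path,
                                           exemplar_lexicon):
        paradigms = build_labeled_paradigms(exemplar_lexicon)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_flexit_table(exemplar_lexicon, paradigms, a)
        write_flexit_table(exemplar_lexicon, paradigms, b)
        assert a.read_bytes() == b.read_bytes()

    def test_unlabelled_lemma_is_fatal(self, tmp_path, exemplar_lexicon):
        with pytest.raises(LexiconFormatError, match="libro"):
            write_flexit_table(
                Lexicon([entry("libro", "libro", N, M, SG, 1)],
                        corpus_size=10),
                [], tmp_path / "x.tsv")


def test_generated_lexicon_round_trip_identity(tmp_path):
    """Write-then-read is the identity on generated data as well."""
    lex, _ = generate_lexicon(default_config(seed=11, scale=0.02))
    paradigms = build_labeled_paradigms(lex)
    out = tmp_path / "gen.tsv"
    write_flexit_table(lex, paradigms, out)
    back = read_lexicon(out, dialect="flexit", corpus_size=lex.corpus_size)
    assert lex.equals_projection(back)
    assert back.total_tokens == lex.total_tokens
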