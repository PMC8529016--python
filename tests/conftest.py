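"""Shared fixtures: a hand-built exemplar lexicon and entry helpers."""

from __future__ import annotations

import pytest

from flexent.types import Gender, LexEntry, Lexicon, Number, Pos

N, A = Pos.NOUN, Pos.ADJECTIVE
F, M = Gender.F, Gender.M
SG, PL = Number.SG, Number.PL


def entry(form, lemma, pos, gender, number, freq=10, grade=None):
    return LexEntry(form=form, lemma=lemma, pos=pos, gender=gender,
                    number=number, token_freq=freq, grade=grade)


@pytest.fixture(scope="session")
def exemplar_lexicon() -> Lexicon:
    """Twelve textbook noun/adjective lemmas, one per inflection pattern.

    Covers every declensional class of the analysis: the five canonical
    noun classes (libro o_i, rosa a_e, fiore e_i, problema a_i, uovo
    o_a with its gender-changing plural), invariance (re, portavoce),
    loanword inflection (sport/sports), class-intersection homography
    (cameriere M.SG = cameriera's F.PL), gender syncretism in the
    singular (abitante), and the two major adjective classes (bello
    "a_e o_i", grande "e_i e_i").
    """
    entries = [
        entry("libro", "libro", N, M, SG, 100),
        entry("libri", "libro", N, M, PL, 40),
        entry("rosa", "rosa", N, F, SG, 50),
        entry("rose", "rosa", N, F, PL, 30),
        entry("fiore", "fiore", N, M, SG, 60),
        entry("fiori", "fiore", N, M, PL, 25),
        entry("problema", "problema", N, M, SG, 70),
        entry("problemi", "problema", N, M, PL, 35),
        entry("uovo", "uovo", N, M, SG, 20),
        entry("uova", "uovo", N, F, PL, 22),
        entry("re", "re", N, M, SG, 90),
        entry("re", "re", N, M, PL, 90),
        entry("sport", "sport", N, M, SG, 80),
        entry("sports", "sport", N, M, PL, 5),
        entry("abitante", "abitante", N, F, SG, 240),
        entry("abitante", "abitante", N, M, SG, 240),
        entry("abitanti", "abitante", N, M, PL, 150),
        entry("cameriere", "cameriere", N, M, SG, 5232),
        entry("camerieri", "cameriere", N, M, PL, 300),
        entry("cameriera", "cameriera", N, F, SG, 200),
        entry("cameriere", "cameriera", N, F, PL, 5232),
        entry("portavoce", "portavoce", N, F, SG, 43),
        entry("portavoce", "portavoce", N, F, PL, 43),
        entry("portavoce", "portavoce", N, M, SG, 43),
        entry("portavoce", "portavoce", N, M, PL, 43),
        entry("bella", "bello", A, F, SG, 55),
        entry("belle", "bello", A, F, PL, 45),
        entry("bello", "bello", A, M, SG, 65),
        entry("belli", "bello", A, M, PL, 35),
        entry("grande", "grande", A, F, SG, 88),
        entry("grandi", "grande", A, F, PL, 77),
        entry("grande", "grande", A, M, SG, 88),
        entry("grandi", "grande", A, M, PL, 77),
    ]
    return Lexicon(entries, corpus_size=1_000_000)
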