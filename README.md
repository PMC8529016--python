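# flexent

Form–value transparency of Italian noun and adjective inflection,
measured as Shannon entropy over an annotated word-form frequency
lexicon.

## The problem

Italian marks gender (F/M) and number (SG/PL) on nouns and adjectives
with a single fused final vowel, drawn from just four letters: *-a,
-e, -i, -o*. The mapping between these endings and the feature values
they express is not one-to-one: *-e* can be a feminine singular
(*tigre*), a feminine plural (*gatte*), or a masculine singular
(*fiore*), and lemmas are spread over declensional classes (*gatt-o /
gatt-i* vs *fior-e / fior-i*) that are only loosely associated with
gender. Psycholinguistic work needs a quantitative handle on this
(in)consistency: how reliably does an ending, or a class, signal a
feature value?

`flexent` answers this with entropy. For each conditioner *c* (an
inflectional ending, or a declensional class) it builds the
distribution of word forms over the feature-value categories *v* —
the four combinations F.SG, F.PL, M.SG, M.PL for endings and
adjective classes, the two genders for noun classes — and reports

    H(c) = − Σ_v p_v · log2 p_v ,   p_v = c_v / Σ_v c_v

in bits. H = 0 means the ending (class) is a fully transparent cue to
one value; the maximum (2 bits over four combinations, 1 bit over
gender) means it carries no information about the value. Counts are
computed twice: over **types** (each distinct form counted once per
attested combination) and over **tokens** (corpus frequencies summed).

The pipeline covers the whole path from raw data to report:

1. **lexicon_io** — read/merge/write annotated frequency lexica
   (TSV; configurable column dialects; per-million standardization);
2. **paradigm_builder** — strip the final character as the ending,
   reconstruct per-lemma paradigms (two cells for nouns, four for
   adjectives), and assign declensional classes (`o_i`, `a_e`, `e_i`,
   `a_i`, `o_a`, `o_a_i`, `Inv`, `Other`; adjective labels like
   `a_e o_i`);
3. **ambiguity** — detect within-POS homographs (forms attested under
   ≥ 2 feature combinations, e.g. *cameriere* M.SG / F.PL) and apply
   the counting policy: ambiguous forms keep their types but their
   undividable token frequencies are excluded;
4. **entropy_report** — build the type/token distributions per ending
   and per class and render the entropy tables;
5. **synthetic_lexicon** — a seeded generator producing lexica with
   the same structure (class mixtures, defective paradigms, planted
   homographs, Zipfian frequencies) so everything is testable without
   external data.

## Worked example

```python
from flexent import LexEntry, Lexicon, Pos, Gender, Number, analyze
from flexent.entropy_report import render_entropy_table

rows = [
    ("gatto", "gatto", "M", "SG", 9_100), ("gatti", "gatto", "M", "PL", 4_300),
    ("gatta", "gatta", "F", "SG", 800),   ("gatte", "gatta", "F", "PL", 300),
    ("fiore", "fiore", "M", "SG", 6_200), ("fiori", "fiore", "M", "PL", 5_100),
    ("tigre", "tigre", "F", "SG", 1_900), ("tigri", "tigre", "F", "PL", 1_200),
    ("analisi", "analisi", "F", "SG", 7_400), ("analisi", "analisi", "F", "PL", 7_400),
]
entries = [LexEntry(f, l, Pos.NOUN, Gender(g), Number(n), tf)
           for f, l, g, n, tf in rows]
report = analyze(Lexicon(entries, corpus_size=1_000_000))

for p in report.paradigms:
    print(p.lemma, p.gender_key.value, p.class_label)
frame = render_entropy_table(report.tables[("noun", "ending", "token")],
                             "noun_ending_token.tsv")
print(frame.to_string(index=False))
```

prints the reconstructed classes

```
analisi F Inv
fiore M e_i
gatta F a_e
gatto M o_i
tigre F e_i
```

and the token-level ending table

```
ending  F.PL  F.SG  M.PL  M.SG   p_F.PL   p_F.SG   p_M.PL   p_M.SG  total      H
     a     0   800     0     0 (0.0000) (1.0000) (0.0000) (0.0000)    800 0.0000
     e   300  1900     0  6200 (0.0357) (0.2262) (0.0000) (0.7381)   8400 0.9801
     i  1200     0  9400     0 (0.1132) (0.0000) (0.8868) (0.0000)  10600 0.5095
     o     0     0     0  9100 (0.0000) (0.0000) (0.0000) (1.0000)   9100 0.0000
 other     0     0     0     0      (-)      (-)      (-)      (-)      0      -
```

Reading: *-a* and *-o* are perfectly transparent here (H = 0, they
only ever mark F.SG and M.SG), *-i* leans masculine-plural
(H ≈ 0.51 bits) and *-e* is the ambiguous ending (H ≈ 0.98 bits,
split over three value combinations). Note that *analisi* —
invariant, hence attested as both F.SG and F.PL — is detected as an
ambiguous form and its 7,400 tokens are excluded from the token
table, while its two types still count in the type table.

The same analysis is available from the shell:

```sh
flexent synth --seed 7 --out lexicon.tsv          # synthetic data
flexent paradigms --lexicon lexicon.tsv --out classes.tsv
flexent ambig     --lexicon lexicon.tsv --pos noun --out patterns.tsv
flexent entropy   --lexicon lexicon.tsv --out-dir reports/
```

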