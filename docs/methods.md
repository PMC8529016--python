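# Methods

## The measure

The package quantifies how consistently an inflectional form cues a
grammatical value in Italian nouns and adjectives. The conditioners
are (i) the four core inflectional endings *-a, -e, -i, -o* and (ii)
the declensional classes; the outcomes are the gender × number
feature combinations F.SG, F.PL, M.SG, M.PL. For each conditioner a
count vector over outcome categories is turned into Shannon entropy
in bits, H = −Σ p·log2 p, with 0·log 0 := 0. Noun paradigms have two
cells (number only; a noun's gender is lexical), so noun-class
entropy is taken over gender and is capped at 1 bit; adjective
paradigms have four cells (gender and number are imposed by
agreement), so adjective distributions run over the four combinations
and are capped at 2 bits. Low H means a transparent form–value
mapping.

Every distribution is computed in two units. **Type** counts treat
each distinct (form, combination) pair as one observation.
**Token** counts sum corpus frequencies. Because corpus frequencies
are tagged at the part-of-speech level only, the tokens of a form
attested under several combinations within one POS cannot be divided
among them; the counting policy therefore keeps ambiguous forms in
the type counts (once per combination) but excludes their tokens
entirely. Token tables are computed over non-ambiguous forms only.

## Paradigm reconstruction and class labels

The ending is the final character of the NFC-normalized, case-folded
form; characters outside {a, e, i, o} are carried verbatim but
grouped as OTHER and reported in a remainder line of the ending
tables rather than as rows of their own.

Nouns are grouped by (lemma, gender): homographic lemma pairs of
different gender (*musicista* M / F) are separate two-cell paradigms.
Two exceptions couple across genders, keyed by the gender of the
singular: gender-changing plurals (one SG and one PL entry of
opposite gender, *uovo* M.SG / *uova* F.PL → `o_a`) and over-abundant
plurals (one SG, two PL entries with distinct endings, *braccio /
braccia / bracci* → `o_a_i`). Identical singular and plural forms
always take priority as invariance (`Inv`), before any ending-pair
classification. Two-cell paradigms whose ending pair is none of
`o_i, a_e, e_i, a_i, o_a` are labelled `Other` (loanword plurals such
as *sport/sports*). Paradigms with only one attested cell are
labelled `e_NA` / `NA_i` style and are excluded from the noun class
tables (they are defective observations, not classes); they still
feed the ending tables.

Adjectives are grouped by lemma into a four-cell paradigm; the label
renders the feminine and masculine SG_PL ending pairs side by side
(`a_e o_i`, `e_i e_i`), with `NA` for an unattested cell and a bare
`NA` for a fully unattested gender (`a_NA NA`, `NA o_i`). An
adjective attested with one identical form across both numbers is
labelled `Inv`; the published class tables contain no such row, so
this label is this package's mechanical extension of the grammar.
Where several forms compete for one cell (e.g. graded forms), the
positive-grade, highest-frequency form defines the cell; grade is
otherwise metadata only.

## Ambiguity

A form is ambiguous when it is attested under ≥ 2 distinct feature
combinations within one POS — regardless of whether that arises from
incidental lemma homography (*latte*), class intersection
(*cameriere*), or invariance (*portavoce*, and every invariant lemma,
whose one form spans both numbers). Homography across POS is not
ambiguity, because POS-level tagging keeps those frequencies apart.
Pattern tables count forms per combination set, four-way patterns
first.

A consequence of the token policy worth stating: since every
invariant lemma's form is ambiguous by construction, the `Inv` (and
planted four-way) classes have empty token rows; empty rows render
their entropy as `-`. Type tables are unaffected.

## The synthetic generator

The generator emulates the post-merge state of a POS-tagged corpus
frequency list joined with a morphological annotation:

* **Stems** are unique CV-alternating strings over a fixed alphabet,
  consonant-final and at least three characters, so the appended
  vowel is always the ending and never stem material; uniqueness
  makes every homograph deliberate.
* **Classes** are sampled per a configurable list of (class label,
  lemma count, p_masculine, cell dropout). The default configuration
  mirrors the published inventory of Italian at one tenth scale:
  nouns o_i 1,196 lemmas (p_M ≈ 0.9998), a_e 832 (p_M = 0), e_i 718
  (p_M ≈ 0.545), a_i 94, o_a 5, o_a_i 6, Inv 4, Other 14; adjectives
  a_e o_i 614, e_i e_i 15, plus the defective NA classes. Defaults
  use 3% noun and 5% a_e-o_i-adjective cell dropout to produce the
  defective paradigms real annotations show.
* **Frequencies** follow freq(rank) = max(1, round(F·rank^−s)) with
  ranks assigned by a seeded shuffle over all distinct (form, POS)
  jointly, mirroring a corpus-wide frequency list. Defaults: s = 1
  (the classic word-frequency regime), F = 10^7 for the rank-1 form,
  nominal corpus size 1.9·10^9 tokens for per-million
  standardization. Homograph entries share their form's undivided
  frequency, as a POS-level merge would produce.
* **Planted homographs**: at `ambiguity_rate` (fraction of distinct
  forms; default 0.005), pairs of forms from compatible classes are
  forced to coincide — an e_i masculine's singular with an a_e
  feminine's plural (the *cameriere* pattern), then dual-gender
  invariants attested in all four combinations (the *portavoce*
  pattern). Planted cells are immune to dropout. Requests beyond the
  capacity of the configured classes degrade to the possible number
  with a warning. Structural ambiguity (invariant lemmas, the
  gender-syncretic cells of `e_i e_i` adjectives) arises on top of
  the planted rate, and the generator's attestation bookkeeping —
  the oracle the detector is tested against — includes both.

What the generator does **not** emulate: Italian phonotactics and
real stem/lemma identities, morphophonological alternations (velar
insertion is invisible at the final character anyway), derivational
morphology, grade morphology beyond the metadata field, semantic
structure, and annotation noise other than missing cells. Passing
tests therefore show that the pipeline's logic is correct under the
stated structural assumptions, not that any particular natural
corpus satisfies them.

## Numerical and formatting choices

* Entropy uses base-2 logarithms throughout; a single-support
  distribution gives exactly 0.0; all-zero count vectors are a
  caller error (report code renders such rows with H = `-`).
* Reports print proportions and H to four decimals, ties rounded
  half away from zero; proportions are row-internal (per
  conditioner).
* Standardized frequency is occurrences per million corpus tokens,
  freq·10^6/corpus_size — the convention of the corpus literature;
  the raw count is what is stored.
* Duplicate (form, pos, gender, number, lemma) input rows have their
  frequencies summed (sharded exports are common); rows with unknown
  codes are rejected and tallied, and a file rejecting more than
  half its rows aborts as a dialect mismatch.
* Output tables are byte-deterministic: fixed row order
  (pos, lemma, gender, number, form) for the lexicon table, endings
  alphabetical and classes by descending total for the reports.

## Problem sizes

The test suite and the acceptance script run the generator at 2–10%
of the published inventory scale (roughly 350–3,700 lemmas,
800–8,200 entries per run) and 10 replicate seeds where sampling
variability matters; the full suite completes in a few seconds.
These sizes keep every class populated, including the small o_a and
Inv classes, while the binomial envelope used for the balanced-class
entropy check is computed analytically at the exact n used.

## Known limitations

* One-cell noun paradigms are excluded from class tables by design;
  a different defectivity convention would change the class totals.
* The token-exclusion policy empties the token rows of invariant
  classes (see above); the published tables print small non-zero
  token counts there, which the stated policy cannot produce — the
  package follows the policy.
* Ambiguity proportions are reported over distinct forms per POS;
  the corresponding published proportions are not exactly
  reproducible from counts alone and are not targeted.
* The generator plants only the two homograph patterns above;
  rarer patterns (three-way mixtures such as *radio* or *marine*)
  occur in real data but are not synthesized.
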