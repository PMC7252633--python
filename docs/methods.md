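# Methods

## Problem and pipeline

Clinical-trial registry records mention genetic variants in free text —
dbSNP rsIDs (`rs12979860`) and protein point mutations (`T790M`,
`Thr790Met`, "leucine to arginine at codon 858") — but carry no structured
variant fields, and their disease annotations are free-form strings plus
MeSH term tags. `trialminer` turns a directory of study-record XML files
into structured mutation–phenotype associations in five stages:

1. **Parse** each XML file into a `TrialRecord` (legacy full-study schema
   tags; unknown elements ignored; absent fields become empty strings).
2. **Mine** the free-text fields — title, summary, description, outcomes,
   keywords, in that fixed order, each as its own sentence block — with two
   rule-based extractors (below).
3. **Normalize** each trial to phenotype nodes through the MeSH chain:
   verbatim MeSH term tags → descriptor ids via a local lexicon TSV →
   Human Phenotype Ontology (HPO) nodes via the MSH/MESH `xref` lines of
   the OBO file → annotated genes via the HPO gene-annotation files.
4. **Associate**: count (mutation, HPO) pairs at trial level (once per
   trial containing both) and mention level (once per textual occurrence),
   plus mutation↔trial, HPO↔trial, HPO↔mutation maps and a per
   intervention-type breakdown.
5. **Report**: static hyperlinked XHTML pages (one per mutation, one per
   trial with mentions, indexes) and deterministic JSON exports, organized
   under ISO-dated snapshot directories so repeated runs can be diffed.

A separate similarity stage treats each HPO node as the binary vector of
mutations it co-occurs with and ranks related phenotype terms by cosine.

## Extraction rules

**rsIDs.** A mention is a maximal token `rs` + digits with no adjacent
letter, digit or underscore on either side; the prefix is matched
case-insensitively and the canonical form is lower-cased. Punctuation does
not block a match (`(rs12979860)` matches), but a trailing letter does:
`rs780094s` is not a mention under the token-boundary rule. This is a
deliberate strictness choice — tokenizers that keep trailing letters
produce spurious "unique" ids that differ from their stems only by
typographical debris.

**Protein point mutations.** A compact ordered grammar of six patterns,
all normalizing to the one-letter canonical `<WT><pos><MT>`:

| pattern | form | example |
|---|---|---|
| P1 | one-letter, uppercase only | `T790M` |
| P2 | three-letter, first letter either case | `Thr790Met` |
| P3 | `<aa> to <aa> at codon <pos>` | leucine to arginine at codon 858 |
| P4 | `<aa>-to-<aa> mutation at codon <pos>` | leucine-to-arginine mutation at codon 858 |
| P5 | `<aa> <pos> to <aa>` | threonine 315 to isoleucine |
| P6 | `<aa> to <aa> mutation at codon <pos>` | leucine to arginine mutation at codon 858 |

Full-name patterns are case-insensitive; positions have no upper bound
(`G20210A` is legitimate); overlapping candidates resolve leftmost-longest
with pattern order as the final tie-break; silent substitutions
(`A123A`) are rejected. Known false-positive classes — cell-line names
(`T47D`), cofactor shorthand (`P4503A`) — are *kept*: they are valid
grammar matches, distinguishing them requires external knowledge the rule
layer does not have, and downstream consumers can suppress them through
the (empty by default) grammar stoplist.

**Sentences.** A deterministic rule-based segmenter (terminal punctuation
+ next-token capitalization heuristic + a small abbreviation list). The
choice of segmenter only affects the sentence context attached to each
mention, never the canonical ids extracted, because both extractors operate
within token boundaries.

## Normalization conventions

- MeSH lexicon lookups are case-insensitive and whitespace-normalized;
  unknown terms are a no-match, never an error. The lexicon is a local
  two-column TSV so the whole pipeline runs offline.
- `MSH:` and `MESH:` xref prefixes are treated as synonyms (OBO releases
  vary). Obsolete terms stay resolvable by id but are excluded from the
  MeSH index. A descriptor mapping to several HPO nodes propagates the
  full set — no arbitrary selection.
- Gene annotations attach directly to their node only; they are **not**
  propagated up the `is_a` hierarchy. Propagation would make every
  ancestor term appear gene-associated and inflate the intervention-type
  gene percentages; direct-only is the conservative reading.
- Condition-string normalization is exact name/synonym matching after
  case-folding, punctuation stripping and whitespace collapsing — no
  stemming or edit distance. Free-form condition spellings ("Diabetes
  Mellitus, Type 1", "Type1diabetes", …) collapse to one node exactly when
  the ontology carries the variants as synonyms.

## Similarity model

Binary incidence: cell (i, j) is 1 iff HPO node i shares at least one
trial with mutation j (trial-mediated co-occurrence, not sentence-level).
Rows are divided by their Euclidean norm; pairwise dot products of unit
rows are cosine similarities, in [0, 1] for nonnegative data, exactly 1
iff two rows have identical support (Cauchy–Schwarz equality). Scores are
symmetric by construction and the implementation enforces this to 1e-12;
a published ranking that prints an asymmetric pair can therefore only be a
typesetting artifact, and no such table is used as numeric ground truth.
Zero-norm rows are flagged and excluded from rankings rather than given
NaN. Ranking ties break lexicographically by HPO id. A count-weighted
incidence (trial counts instead of presence) exists behind a flag, off by
default: the similarity example is defined on presence. Transposing the
matrix clusters mutations by phenotype profile; the implementation
guarantees this equals running the pipeline on the transpose.

## Synthetic corpus

`synthcorpus.generate` is a pure function of its `PlantSpec` (seed in,
bytes out). It emulates: registry XML with the legacy tag set, a
16-node mini-ontology containing the published multicystic-kidney xref
block verbatim plus every xref prefix variant (MSH, MESH, UMLS,
SNOMEDCT_US) and one obsolete node, a MeSH lexicon including a descriptor
with no HPO mapping, gene annotations, and a truth manifest listing every
expected mention, MeSH id, HPO id and gene. Planted protein mutations
cycle through all six grammar surface forms; decoy trials carry vetted
mutation-free prose and near-miss tokens. Defaults (12 trials, 4 decoys,
0–2 SNPs and 0–2 protein mutations per planted trial) are a realistic
miniature of the mined corpus. What it does **not** emulate: the
statistical distribution of real trial metadata, misspelled or truncated
variant tokens, multi-sentence mention contexts, and corpus-scale term
frequencies — so passing end-to-end tests demonstrates correctness of the
mechanics, not recall on real registry prose.

## Problem sizes and numerical choices

The test suite and the acceptance script run the published worked-example
lists as-is (15–75 ids each), 100 seeded random 10×10 matrices against a
double-loop dot-product oracle, and 20 seeded synthetic corpora of 10
trials (3 decoys) each; the whole suite completes in a few seconds.
Percentages in the intervention breakdown use half-even rounding to two
decimals. JSON exports serialize with sorted keys and fixed indentation so
re-export is byte-identical. All randomness flows through explicit seeds.

## Known limitations

- DNA/RNA-level HGVS variants, insertions, deletions and frameshifts are
  out of scope; only rsIDs and protein substitutions are extracted.
- Protein mutations are not mapped to rsIDs.
- The grammar is a compact six-pattern set, not a full reimplementation of
  the ~1500-regex rule bases of the large mutation taggers; surface forms
  outside the six patterns are missed.
- MeSH resolution requires the local lexicon to contain the term; there is
  no online fallback.
- No statistical enrichment testing of associations and no clustering
  beyond ranked cosine lists.
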