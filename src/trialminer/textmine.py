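"""Rule-based extraction of dbSNP rsIDs and protein point mutations.

Two entity classes are mined from clinical-trial free text:

* **SNPs**, written as dbSNP reference-SNP identifiers: the letters ``rs``
  followed by digits (``rs12979860``).  Matching is case-insensitive on the
  prefix and requires a token boundary on both sides, so ``versus`` or a
  bare ``rs`` never match; the canonical form is lower-cased.

* **Protein point mutations**, amino-acid substitutions written in any of a
  compact grammar of surface forms (the wNm family popularized by
  rule-based mutation taggers): ``T790M``, ``Thr790Met``, ``leucine to
  arginine at codon 858``, ``leucine-to-arginine mutation at codon 858``,
  ``threonine 315 to isoleucine``.  All forms normalize to the one-letter
  canonical ``<WT><pos><MT>``; silent changes (WT == MT) are rejected.

Known false-positive classes (cell-line names like ``T47D``, cofactor
shorthand like ``P4503A``) are *not* specially filtered: they are
legitimate matches of the grammar and a pluggable stoplist hook exists for
callers who want them gone.  It ships empty.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from trialminer.corpus_io import TrialRecord

SNP = "SNP"
PROTEIN = "PROTEIN"

#: (one-letter, three-letter, full names) for the 20 standard residues
AMINO_ACIDS: list[tuple[str, str, tuple[str, ...]]] = [
    ("A", "Ala", ("alanine",)),
    ("R", "Arg", ("arginine",)),
    ("N", "Asn", ("asparagine",)),
    ("D", "Asp", ("aspartate", "aspartic acid")),
    ("C", "Cys", ("cysteine",)),
    ("Q", "Gln", ("glutamine",)),
    ("E", "Glu", ("glutamate", "glutamic acid")),
    ("G", "Gly", ("glycine",)),
    ("H", "His", ("histidine",)),
    ("I", "Ile", ("isoleucine",)),
    ("L", "Leu", ("leucine",)),
    ("K", "Lys", ("lysine",)),
    ("M", "Met", ("methionine",)),
    ("F", "Phe", ("phenylalanine",)),
    ("P", "Pro", ("proline",)),
    ("S", "Ser", ("serine",)),
    ("T", "Thr", ("threonine",)),
    ("W", "Trp", ("tryptophan",)),
    ("Y", "Tyr", ("tyrosine",)),
    ("V", "Val", ("valine",)),
]

ONE_LETTER = "".join(a for a, _, _ in AMINO_ACIDS)
THREE_TO_ONE = {three: one for one, three, _ in AMINO_ACIDS}
NAME_TO_ONE = {name: one for one, _, names in AMINO_ACIDS for name in names}

_RSID_RE = re.compile(r"(?<![A-Za-z0-9_])[Rr][Ss](\d+)(?![A-Za-z0-9_])")

_THREE_ALT = "|".join(f"[{t[0]}{t[0].lower()}]{t[1:]}" for t in THREE_TO_ONE)
_NAME_ALT = "|".join(re.escape(n) for n in sorted(NAME_TO_ONE, key=len, reverse=True))
_POS = r"[1-9]\d*"


def _aa_to_one(token: str) -> str:
    """Normalize a residue token (one-letter, three-letter, or full name)."""
    if len(token) == 1:
        return token.upper()
    if len(token) == 3 and token.capitalize() in THREE_TO_ONE:
        return THREE_TO_ONE[token.capitalize()]
    return NAME_TO_ONE[token.lower()]


@dataclass
class MutationMention:
    """One extracted mention of an SNP or protein point mutation."""

    kind: str  # SNP | PROTEIN
    raw: str
    canonical: str
    sentence: str
    trial_id: str = ""
    char_offset: int = 0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "raw": self.raw,
            "canonical": self.canonical,
            "sentence": self.sentence,
            "trial_id": self.trial_id,
            "char_offset": self.char_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MutationMention":
        return cls(**d)


@dataclass
class MutationGrammar:
    """Ordered pattern set for protein point mutations.

    Patterns (applied leftmost-longest across the whole set):

    P1  one-letter ``<WT><pos><MT>``, uppercase only, no flanking
        alphanumerics (``T790M``);
    P2  three-letter ``<Xaa><pos><Yaa>``, case-insensitive on the first
        letter (``Thr790Met``);
    P3  ``<aa> to <aa> at codon <pos>``;
    P4  ``<aa>-to-<aa> mutation at codon <pos>``;
    P5  ``<aa> <pos> to <aa>``;
    P6  ``<aa> to <aa> mutation at codon <pos>``.

    ``stoplist`` holds canonical forms to suppress; it ships empty because
    the grammar's known false-positive classes are kept by design.
    """

    patterns: list[tuple[str, re.Pattern]] = field(default_factory=list)
    stoplist: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.patterns:
            self.patterns = _default_patterns()

    def finditer(self, sentence: str) -> list[tuple[int, int, str, str, str, str]]:
        """All non-overlapping grammar matches in a sentence.

        Returns (start, end, raw, wt, pos, mt) tuples in document order,
        resolved leftmost-longest with the pattern order as final
        tie-break.  WT == MT candidates are rejected.
        """
        candidates: list[tuple[int, int, int, str, str, str, str]] = []
        for order, (_, pattern) in enumerate(self.patterns):
            for m in pattern.finditer(sentence):
                wt = _aa_to_one(m.group("wt"))
                mt = _aa_to_one(m.group("mt"))
                if wt == mt:
                    continue
                pos = str(int(m.group("pos")))
                if wt + pos + mt in self.stoplist:
                    continue
                candidates.append((m.start(), -(m.end() - m.start()), order, m.group(0), wt, pos, mt))
        candidates.sort()
        chosen: list[tuple[int, int, str, str, str, str]] = []
        last_end = -1
        for start, neg_len, _, raw, wt, pos, mt in candidates:
            end = start - neg_len
            if start >= last_end:
                chosen.append((start, end, raw, wt, pos, mt))
                last_end = end
        return chosen


def _default_patterns() -> list[tuple[str, re.Pattern]]:
    return [
        (
            "P1",
            re.compile(
                rf"(?<![A-Za-z0-9_])(?P<wt>[{ONE_LETTER}])(?P<pos>{_POS})"
                rf"(?P<mt>[{ONE_LETTER}])(?![A-Za-z0-9_])"
            ),
        ),
        (
            "P2",
            re.compile(
                rf"(?<![A-Za-z0-9_])(?P<wt>{_THREE_ALT})(?P<pos>{_POS})"
                rf"(?P<mt>{_THREE_ALT})(?![A-Za-z0-9_])"
            ),
        ),
        (
            "P3",
            re.compile(
                rf"\b(?P<wt>{_NAME_ALT})\s+to\s+(?P<mt>{_NAME_ALT})\s+at\s+codon\s+(?P<pos>{_POS})\b",
                re.IGNORECASE,
            ),
        ),
        (
            "P4",
            re.compile(
                rf"\b(?P<wt>{_NAME_ALT})[-‐‑–]to[-‐‑–](?P<mt>{_NAME_ALT})"
                rf"\s+mutation\s+at\s+codon\s+(?P<pos>{_POS})\b",
                re.IGNORECASE,
            ),
        ),
        (
            "P5",
            re.compile(
                rf"\b(?P<wt>{_NAME_ALT})\s+(?P<pos>{_POS})\s+to\s+(?P<mt>{_NAME_ALT})\b",
                re.IGNORECASE,
            ),
        ),
        (
            "P6",
            re.compile(
                rf"\b(?P<wt>{_NAME_ALT})\s+to\s+(?P<mt>{_NAME_ALT})\s+mutation\s+at\s+codon\s+(?P<pos>{_POS})\b",
                re.IGNORECASE,
            ),
        ),
    ]


_DEFAULT_GRAMMAR: MutationGrammar | None = None


def default_grammar() -> MutationGrammar:
    """Shared default grammar instance (patterns are immutable once built)."""
    global _DEFAULT_GRAMMAR
    if _DEFAULT_GRAMMAR is None:
        _DEFAULT_GRAMMAR = MutationGrammar()
    return _DEFAULT_GRAMMAR


# --- sentence segmentation ---------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "al", "fig", "dr", "mr", "mrs", "ms", "st",
    "no", "approx", "ca", "resp",
}

_BOUNDARY_RE = re.compile(r"(?P<punct>[.!?]+[\"'\)\]]*)(?P<space>\s+)")


def split_sentences(text: str) -> list[str]:
    """Deterministic rule-based sentence segmentation.

    Splits at sentence-final punctuation followed by whitespace and a
    plausible sentence opener (capital letter, digit, bracket/quote, or an
    ``rs`` token), with a small abbreviation list to suppress spurious
    breaks.  Only whitespace is consumed at boundaries, so the
    concatenation of the sentences equals the input up to boundary
    whitespace.
    """
    sentences: list[str] = []
    for block in re.split(r"\n+", text):
        block = block.strip()
        if not block:
            continue
        start = 0
        for m in _BOUNDARY_RE.finditer(block):
            nxt = m.end()
            if nxt >= len(block):
                break
            nc = block[nxt]
            if not (nc.isupper() or nc.isdigit() or nc in "\"'([" or block.startswith("rs", nxt)):
                continue
            prev = re.search(r"([A-Za-z][A-Za-z.]*)$", block[: m.start()])
            if prev and prev.group(1).lower().rstrip(".") in _ABBREVIATIONS:
                continue
            sentence = block[start : m.start() + len(m.group("punct"))].strip()
            if sentence:
                sentences.append(sentence)
            start = m.end()
        tail = block[start:].strip()
        if tail:
            sentences.append(tail)
    return sentences


# --- extraction --------------------------------------------------------------

def _rsids_in_sentence(sentence: str, trial_id: str) -> list[MutationMention]:
    return [
        MutationMention(
            kind=SNP,
            raw=m.group(0),
            canonical="rs" + m.group(1),
            sentence=sentence,
            trial_id=trial_id,
            char_offset=m.start(),
        )
        for m in _RSID_RE.finditer(sentence)
    ]


def _proteins_in_sentence(
    sentence: str, trial_id: str, grammar: MutationGrammar
) -> list[MutationMention]:
    return [
        MutationMention(
            kind=PROTEIN,
            raw=raw,
            canonical=wt + pos + mt,
            sentence=sentence,
            trial_id=trial_id,
            char_offset=start,
        )
        for start, _end, raw, wt, pos, mt in grammar.finditer(sentence)
    ]


def extract_rsids(text: str, trial_id: str = "") -> list[MutationMention]:
    """Extract every dbSNP rsID mention from free text, in document order.

    A mention is a maximal ``rs`` + digits token at a token boundary;
    adjacent punctuation (``(rs12979860)``) does not block the match.
    Canonical ids are lower-cased.
    """
    mentions: list[MutationMention] = []
    for sentence in split_sentences(text):
        mentions.extend(_rsids_in_sentence(sentence, trial_id))
    return mentions


def extract_protein_mutations(
    text: str, trial_id: str = "", grammar: MutationGrammar | None = None
) -> list[MutationMention]:
    """Extract protein point-mutation mentions from free text.

    All grammar surface forms normalize to the one-letter canonical;
    overlaps resolve leftmost-longest; silent substitutions are dropped.
    """
    grammar = grammar or default_grammar()
    mentions: list[MutationMention] = []
    for sentence in split_sentences(text):
        mentions.extend(_proteins_in_sentence(sentence, trial_id, grammar))
    return mentions


def mine_trial(record: TrialRecord, grammar: MutationGrammar | None = None) -> list[MutationMention]:
    """Run both extractors over a trial's mined text fields.

    Fields are processed in the fixed order (title, summary, description,
    outcomes, keywords), each as its own sentence block; within a sentence,
    SNP and protein matches are merged in character order, so the returned
    mention list is in document order.
    """
    grammar = grammar or default_grammar()
    mentions: list[MutationMention] = []
    for field_text in record.mined_fields():
        for sentence in split_sentences(field_text):
            found = _rsids_in_sentence(sentence, record.trial_id)
            found += _proteins_in_sentence(sentence, record.trial_id, grammar)
            found.sort(key=lambda m: m.char_offset)
            mentions.extend(found)
    return mentions
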