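"""Read clinical-trial registry XML files and the local MeSH lexicon.

Study records follow the legacy ClinicalTrials.gov full-study XML schema
(``<nct_id>``, ``<brief_title>``, ``<brief_summary>``, ``<condition>``,
``<mesh_term>``, ``<intervention_type>``, ``<phase>`` ...).  Unrecognized
elements are ignored and every text field defaults to the empty string, so
minor schema dialects degrade per-field rather than failing the record.

MeSH descriptor ids are resolved from a local two-column TSV lexicon
(``term<TAB>D-number``) so the whole pipeline runs offline and
reproducibly.
"""

from __future__ import annotations

import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

_MESH_ID_RE = re.compile(r"^[A-Za-z]\d+$")


class CorpusError(Exception):
    """Base error for corpus input problems."""


class TrialParseError(CorpusError):
    """Malformed trial XML; the message names the offending source."""


class TrialValidationError(CorpusError):
    """Structurally valid XML that violates a record invariant (e.g. no id)."""


class LexiconError(CorpusError):
    """Invalid MeSH lexicon table (e.g. one term mapped to two ids)."""


@dataclass
class TrialRecord:
    """One parsed clinical-trial document.

    Text fields are never ``None``: absent XML elements yield empty strings
    (or empty lists for repeated elements).  ``mesh_terms`` are preserved
    verbatim — case and punctuation intact — because the MeSH lexicon lookup
    normalizes on its side.
    """

    trial_id: str
    title: str = ""
    summary: str = ""
    description: str = ""
    outcomes: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    intervention_types: list[str] = field(default_factory=list)
    phase: str = ""
    study_type: str = ""
    keywords: list[str] = field(default_factory=list)

    def mined_fields(self) -> list[str]:
        """Free-text fields submitted to mutation mining, in fixed order.

        Order: title, summary, description, outcomes, keywords.  Each field
        is treated as its own block, which inserts a sentence boundary
        between fields.
        """
        fields: list[str] = [self.title, self.summary, self.description]
        fields.extend(self.outcomes)
        fields.extend(self.keywords)
        return [f for f in fields if f]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(**d)


def _clean(text: str | None) -> str:
    """Collapse the whitespace padding typical of registry textblocks."""
    if not text:
        return ""
    return re.sub(r"\s+", " ", text).strip()


def _textblock(elem: ET.Element) -> str:
    """Text of an element, preferring a nested <textblock> child."""
    block = elem.find("textblock")
    if block is not None:
        return _clean(block.text)
    return _clean("".join(elem.itertext()))


def parse_trial_xml(xml_document: str, source: str = "<string>") -> TrialRecord:
    """Parse one study-record XML document into a :class:`TrialRecord`.

    Parameters
    ----------
    xml_document:
        Full XML text of a single trial.
    source:
        Name used in error messages (typically the file path).

    Raises
    ------
    TrialParseError
        If the XML is not well formed.
    TrialValidationError
        If no non-empty trial id element is present.
    """
    try:
        root = ET.fromstring(xml_document)
    except ET.ParseError as exc:
        raise TrialParseError(f"malformed XML in {source}: {exc}") from exc

    id_elem = root.find(".//nct_id")
    trial_id = _clean(id_elem.text if id_elem is not None else "")
    if not trial_id:
        raise TrialValidationError(f"missing trial id (<nct_id>) in {source}")

    title_elem = root.find(".//brief_title")
    if title_elem is None:
        title_elem = root.find(".//official_title")
    summary_elem = root.find(".//brief_summary")
    desc_elem = root.find(".//detailed_description")

    outcomes: list[str] = []
    for tag in ("primary_outcome", "secondary_outcome", "other_outcome"):
        for elem in root.iter(tag):
            text = " ".join(_clean(t) for t in elem.itertext() if _clean(t))
            if text:
                outcomes.append(text)

    phase_elem = root.find(".//phase")
    study_type_elem = root.find(".//study_type")

    return TrialRecord(
        trial_id=trial_id,
        title=_clean(title_elem.text if title_elem is not None else ""),
        summary=_textblock(summary_elem) if summary_elem is not None else "",
        description=_textblock(desc_elem) if desc_elem is not None else "",
        outcomes=outcomes,
        conditions=[_clean(e.text) for e in root.iter("condition") if _clean(e.text)],
        mesh_terms=[(e.text or "").strip() for e in root.iter("mesh_term") if (e.text or "").strip()],
        intervention_types=[_clean(e.text) for e in root.iter("intervention_type") if _clean(e.text)],
        phase=_clean(phase_elem.text if phase_elem is not None else ""),
        study_type=_clean(study_type_elem.text if study_type_elem is not None else ""),
        keywords=[_clean(e.text) for e in root.iter("keyword") if _clean(e.text)],
    )


def scan_corpus(directory: str | Path) -> Iterator[TrialRecord]:
    """Yield one :class:`TrialRecord` per parseable ``.xml`` file.

    Per-file parse or validation errors are logged and skipped; the total
    skip count is logged at the end.  An unreadable directory raises OSError.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NotADirectoryError(f"not a readable corpus directory: {directory}")
    paths = sorted(directory.glob("*.xml"))
    if not paths:
        logger.warning("no .xml files found in %s", directory)
    skipped = 0
    for path in paths:
        try:
            yield parse_trial_xml(path.read_text(encoding="utf-8"), source=str(path))
        except CorpusError as exc:
            skipped += 1
            logger.warning("skipping %s: %s", path, exc)
    if skipped:
        logger.info("scan_corpus: skipped %d of %d files", skipped, len(paths))


def write_records_ndjson(records: list[TrialRecord], path: str | Path) -> None:
    """Serialize records as newline-delimited JSON for pipeline handoff."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True, ensure_ascii=False) + "\n")


def read_records_ndjson(path: str | Path) -> list[TrialRecord]:
    with open(path, encoding="utf-8") as fh:
        return [TrialRecord.from_dict(json.loads(line)) for line in fh if line.strip()]


def _norm_term(term: str) -> str:
    """Lexicon lookup key: case-folded, whitespace-collapsed."""
    return re.sub(r"\s+", " ", term).strip().casefold()


@dataclass
class MeshLexicon:
    """Bidirectional MeSH term <-> descriptor-id table.

    Lookups are case-insensitive and whitespace-normalized; unknown terms
    return ``None`` rather than raising, so the lookup is total.
    """

    term_to_id: dict[str, str] = field(default_factory=dict)
    id_to_term: dict[str, str] = field(default_factory=dict)
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {_norm_term(t): i for t, i in self.term_to_id.items()}

    def lookup(self, term: str) -> str | None:
        """Return the D-number for a term, or ``None`` if unknown."""
        return self._index.get(_norm_term(term))

    def term_for(self, mesh_id: str) -> str | None:
        return self.id_to_term.get(mesh_id)

    def __len__(self) -> int:
        return len(self.term_to_id)


def load_mesh_lexicon(tsv: str | Path) -> MeshLexicon:
    """Load a two-column ``term<TAB>D-number`` TSV into a :class:`MeshLexicon`.

    A header row is tolerated (detected by its second column not looking
    like a descriptor id).  A term appearing twice with conflicting ids is a
    validation error naming the term; an id with several preferred terms
    keeps the first.
    """
    term_to_id: dict[str, str] = {}
    id_to_term: dict[str, str] = {}
    index: dict[str, str] = {}
    with open(tsv, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LexiconError(f"{tsv}:{lineno}: expected 2 tab-separated columns")
            term, mesh_id = parts[0].strip(), parts[1].strip()
            if not _MESH_ID_RE.match(mesh_id):
                if lineno == 1:  # header row
                    continue
                raise LexiconError(f"{tsv}:{lineno}: invalid MeSH id {mesh_id!r}")
            key = _norm_term(term)
            if key in index and index[key] != mesh_id:
                raise LexiconError(
                    f"conflicting ids for term {term!r}: {index[key]} vs {mesh_id}"
                )
            index[key] = mesh_id
            term_to_id.setdefault(term, mesh_id)
            id_to_term.setdefault(mesh_id, term)
    return MeshLexicon(term_to_id=term_to_id, id_to_term=id_to_term, _index=index)
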