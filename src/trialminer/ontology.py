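"""HPO ontology parsing and the MeSH-xref index that drives normalization.

The Human Phenotype Ontology ships as an OBO flat file whose ``[Term]``
stanzas carry ``xref:`` lines into MeSH, UMLS and SNOMED CT.  Inverting the
MeSH xrefs yields the D-number -> HP-id map used to normalize clinical
trials (tagged with MeSH terms) onto phenotype nodes.  Gene annotations come
from the tab-separated HPO annotation files and are attached directly to
nodes — no propagation up the is_a hierarchy.

OBO parsing is delegated to :mod:`obonet`; this module reshapes its graph
into the lookup structures the pipeline needs.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import obonet

logger = logging.getLogger(__name__)

HPO_ID_RE = re.compile(r"^HP:\d{7}$")

#: xref prefixes treated as MeSH (OBO releases vary between the two spellings)
_MESH_PREFIXES = {"MSH", "MESH"}

_SYNONYM_RE = re.compile(r'"([^"]*)"')


@dataclass
class OntologyNode:
    """One HPO term: id, name, synonyms, parent edges and external xrefs."""

    hpo_id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    xrefs: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False


@dataclass
class AnnotationReport:
    """Row accounting from the last :func:`parse_annotations` call."""

    n_rows: int = 0
    n_added: int = 0
    n_dropped: int = 0


@dataclass
class Ontology:
    """Parsed HPO: node table, MeSH-id index, and gene annotations.

    ``mesh_index`` is exactly the inversion of all MSH/MESH-prefixed xrefs of
    non-obsolete nodes.  ``gene_annotations`` keys are always known node ids;
    annotation rows for unknown ids are dropped (and counted).
    """

    nodes: dict[str, OntologyNode] = field(default_factory=dict)
    mesh_index: dict[str, set[str]] = field(default_factory=dict)
    gene_annotations: dict[str, set[str]] = field(default_factory=dict)
    annotation_report: AnnotationReport = field(default_factory=AnnotationReport)

    def name_of(self, hpo_id: str) -> str:
        node = self.nodes.get(hpo_id)
        return node.name if node else ""

    def name_index(self) -> dict[str, str]:
        """Map normalized name/synonym -> hpo_id for condition matching.

        Normalization strips punctuation, case-folds, and collapses
        whitespace; obsolete nodes are excluded.  On a normalized-name
        collision the lexicographically smallest id wins (deterministic).
        """
        index: dict[str, str] = {}
        for hpo_id in sorted(self.nodes):
            node = self.nodes[hpo_id]
            if node.obsolete:
                continue
            for label in [node.name, *node.synonyms]:
                key = normalize_label(label)
                if key and key not in index:
                    index[key] = hpo_id
        return index


def normalize_label(label: str) -> str:
    """Case-/punctuation-insensitive key for condition-name matching."""
    return re.sub(r"\s+", " ", re.sub(r"[^\w\s]", " ", label)).strip().casefold()


def parse_obo(obo_text: str | Path) -> Ontology:
    """Parse an OBO flat file (text or path) into an :class:`Ontology`.

    Every ``[Term]`` stanza becomes a node; ``is_a`` lines become parent
    edges; ``xref:`` lines are split at the first colon into (prefix, id)
    pairs.  Obsolete terms are retained for id resolution but excluded from
    the MeSH index.  Dangling ``is_a`` targets are dropped with a warning.
    """
    if isinstance(obo_text, Path):
        handle: io.TextIOBase | Path = obo_text
    else:
        handle = io.StringIO(obo_text)
    graph = obonet.read_obo(handle, ignore_obsolete=False)

    ontology = Ontology()
    for node_id, data in graph.nodes(data=True):
        if not node_id:
            continue
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            if m:
                synonyms.append(m.group(1))
        xrefs = []
        for raw in data.get("xref", []):
            prefix, _, xid = raw.partition(":")
            if xid:
                xrefs.append((prefix.strip(), xid.strip()))
        ontology.nodes[node_id] = OntologyNode(
            hpo_id=node_id,
            name=data.get("name", ""),
            synonyms=synonyms,
            xrefs=xrefs,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )

    for node_id, node in ontology.nodes.items():
        raw_parents = graph.nodes[node_id].get("is_a", [])
        for raw in raw_parents:
            parent = raw.split("!")[0].strip()
            if parent in ontology.nodes:
                node.parents.append(parent)
            else:
                logger.warning("dangling is_a target %s on %s; dropped", parent, node_id)
        if not node.obsolete:
            for prefix, xid in node.xrefs:
                if prefix.upper() in _MESH_PREFIXES:
                    ontology.mesh_index.setdefault(xid, set()).add(node_id)
    return ontology


def parse_annotations(
    tsv: str | Path,
    ontology: Ontology,
    gene_column: int = 1,
    hpo_column: int = 2,
    comment_prefix: str = "#",
) -> Ontology:
    """Attach gene annotations from a tab-separated HPO annotation file.

    The default column layout matches the current ``genes_to_phenotype``
    release (ncbi_gene_id, gene_symbol, hpo_id, ...); both indices are
    configurable because annotation files have reshuffled columns across
    releases.  Duplicate (gene, term) pairs collapse; rows with malformed or
    unknown HPO ids are counted and skipped (see ``ontology.annotation_report``).
    """
    report = AnnotationReport()
    with open(tsv, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(comment_prefix):
                continue
            parts = line.split("\t")
            if len(parts) <= max(gene_column, hpo_column):
                report.n_dropped += 1
                continue
            report.n_rows += 1
            gene = parts[gene_column].strip()
            hpo_id = parts[hpo_column].strip()
            if not HPO_ID_RE.match(hpo_id):
                if report.n_rows == 1 and not gene.isupper():
                    report.n_rows -= 1  # header row
                    continue
                report.n_dropped += 1
                continue
            if hpo_id not in ontology.nodes:
                logger.warning("annotation row for unknown id %s dropped", hpo_id)
                report.n_dropped += 1
                continue
            ontology.gene_annotations.setdefault(hpo_id, set()).add(gene)
            report.n_added += 1
    ontology.annotation_report = report
    return ontology


def mesh_to_hpo(mesh_id: str, ontology: Ontology) -> set[str]:
    """All HPO ids carrying an MSH/MESH xref to ``mesh_id`` (possibly empty).

    Exact id match only — no fuzzy matching.  A MeSH descriptor may map to
    several HPO nodes; the full set is returned.
    """
    return set(ontology.mesh_index.get(mesh_id, set()))


def genes_for_hpo(hpo_id: str, ontology: Ontology) -> set[str]:
    """Gene symbols directly annotated to an HPO term (empty if none)."""
    return set(ontology.gene_annotations.get(hpo_id, set()))
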