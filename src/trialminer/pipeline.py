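"""End-to-end convenience: corpus + ontology + lexicon -> association table."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from trialminer.associate import AnnotatedTrial, AssociationTable, annotate_trial, build_associations
from trialminer.corpus_io import MeshLexicon, TrialRecord, load_mesh_lexicon, scan_corpus
from trialminer.ontology import Ontology, parse_annotations, parse_obo
from trialminer.textmine import MutationGrammar, MutationMention, default_grammar, mine_trial


@dataclass
class PipelineResult:
    """Everything the downstream stages need, from one corpus run."""

    records: list[TrialRecord]
    mentions: dict[str, list[MutationMention]]
    annotated: list[AnnotatedTrial]
    assoc: AssociationTable
    ontology: Ontology
    lexicon: MeshLexicon

    @property
    def total_mentions(self) -> int:
        return sum(len(m) for m in self.mentions.values())


def run_pipeline(
    corpus_dir: str | Path,
    obo_path: str | Path,
    annotations_path: str | Path | None,
    lexicon_path: str | Path,
    grammar: MutationGrammar | None = None,
) -> PipelineResult:
    """Parse, mine, normalize and aggregate one corpus directory."""
    grammar = grammar or default_grammar()
    ontology = parse_obo(Path(obo_path))
    if annotations_path is not None:
        parse_annotations(annotations_path, ontology)
    lexicon = load_mesh_lexicon(lexicon_path)

    records = list(scan_corpus(corpus_dir))
    mentions = {rec.trial_id: mine_trial(rec, grammar) for rec in records}
    annotated = [annotate_trial(rec, mentions[rec.trial_id], lexicon, ontology) for rec in records]
    assoc = build_associations(annotated)
    return PipelineResult(
        records=records,
        mentions=mentions,
        annotated=annotated,
        assoc=assoc,
        ontology=ontology,
        lexicon=lexicon,
    )
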