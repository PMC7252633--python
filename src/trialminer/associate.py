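"""Normalize trials to HPO through the MeSH chain and build counted tables.

The normalization chain is: trial MeSH terms -> MeSH descriptor ids (local
lexicon) -> HPO nodes (MSH xrefs in the ontology) -> annotated genes.  On
top of the annotated trials the module builds the association tables the
reports and the similarity example consume: mutation <-> trial, HPO <->
trial, HPO <-> mutation, per-pair trial- and mention-level counts, and the
per-intervention-type breakdown.

Counting conventions: a (mutation, HPO) pair counts once per trial that
contains both (trial level) and once per mention of the mutation in such a
trial (mention level).  Unique-mutation sets per HPO node are unions over
trials mapped to that node — trial-mediated co-occurrence, not
sentence-level co-occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from trialminer.corpus_io import MeshLexicon, TrialRecord
from trialminer.ontology import Ontology, genes_for_hpo, mesh_to_hpo, normalize_label
from trialminer.textmine import PROTEIN, SNP, MutationMention

#: bucket key for condition strings that match no ontology label
NO_MATCH = "__unmatched__"


@dataclass
class AnnotatedTrial:
    """A trial with its mentions and its resolved MeSH/HPO/gene context."""

    trial_id: str
    mentions: list[MutationMention] = field(default_factory=list)
    mesh_ids: set[str] = field(default_factory=set)
    hpo_ids: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    intervention_types: list[str] = field(default_factory=list)

    @property
    def snp_canonicals(self) -> set[str]:
        return {m.canonical for m in self.mentions if m.kind == SNP}

    @property
    def protein_canonicals(self) -> set[str]:
        return {m.canonical for m in self.mentions if m.kind == PROTEIN}


@dataclass
class PairCount:
    """Trial- and mention-level counts for one (mutation, HPO) pair."""

    trials: int = 0
    mentions: int = 0


@dataclass
class InterventionStats:
    """Per-intervention-type trial count and mapping percentages."""

    n_trials: int
    pct_gene_mapped: float
    pct_rsid: float
    pct_protein: float


@dataclass
class AssociationTable:
    """All counted links among mutations, trials, MeSH ids and HPO nodes."""

    mutation_hpo_counts: dict[tuple[str, str], PairCount] = field(default_factory=dict)
    mutation_trials: dict[str, set[str]] = field(default_factory=dict)
    hpo_trials: dict[str, set[str]] = field(default_factory=dict)
    hpo_mutations: dict[str, set[str]] = field(default_factory=dict)
    mutation_kind: dict[str, str] = field(default_factory=dict)
    trial_mentions: dict[str, list[MutationMention]] = field(default_factory=dict)
    trial_hpo: dict[str, set[str]] = field(default_factory=dict)
    trial_mesh: dict[str, set[str]] = field(default_factory=dict)
    total_mentions: int = 0

    def mutations_of_kind(self, kind: str) -> set[str]:
        return {m for m, k in self.mutation_kind.items() if k == kind}

    # -- serialization (associations.json) ------------------------------------

    def to_dict(self) -> dict:
        return {
            "mutation_hpo_counts": {
                f"{m}\t{h}": {"trials": c.trials, "mentions": c.mentions}
                for (m, h), c in sorted(self.mutation_hpo_counts.items())
            },
            "mutation_trials": {m: sorted(t) for m, t in sorted(self.mutation_trials.items())},
            "hpo_trials": {h: sorted(t) for h, t in sorted(self.hpo_trials.items())},
            "hpo_mutations": {h: sorted(m) for h, m in sorted(self.hpo_mutations.items())},
            "mutation_kind": dict(sorted(self.mutation_kind.items())),
            "trial_mentions": {
                t: [m.to_dict() for m in ms] for t, ms in sorted(self.trial_mentions.items())
            },
            "trial_hpo": {t: sorted(h) for t, h in sorted(self.trial_hpo.items())},
            "trial_mesh": {t: sorted(m) for t, m in sorted(self.trial_mesh.items())},
            "total_mentions": self.total_mentions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationTable":
        table = cls()
        for key, counts in d["mutation_hpo_counts"].items():
            m, h = key.split("\t")
            table.mutation_hpo_counts[(m, h)] = PairCount(**counts)
        table.mutation_trials = {m: set(t) for m, t in d["mutation_trials"].items()}
        table.hpo_trials = {h: set(t) for h, t in d["hpo_trials"].items()}
        table.hpo_mutations = {h: set(m) for h, m in d["hpo_mutations"].items()}
        table.mutation_kind = dict(d["mutation_kind"])
        table.trial_mentions = {
            t: [MutationMention.from_dict(m) for m in ms] for t, ms in d["trial_mentions"].items()
        }
        table.trial_hpo = {t: set(h) for t, h in d["trial_hpo"].items()}
        table.trial_mesh = {t: set(m) for t, m in d["trial_mesh"].items()}
        table.total_mentions = d["total_mentions"]
        return table

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "AssociationTable":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def annotate_trial(
    record: TrialRecord,
    mentions: list[MutationMention],
    lexicon: MeshLexicon,
    ontology: Ontology,
) -> AnnotatedTrial:
    """Resolve a trial's MeSH terms through the lexicon and ontology chain.

    ``hpo_ids`` is the union of ``mesh_to_hpo`` over the resolved MeSH ids;
    ``genes`` the union of ``genes_for_hpo`` over those nodes.  MeSH terms
    absent from the lexicon are simply dropped (the lookup is total).
    """
    mesh_ids: set[str] = set()
    for term in record.mesh_terms:
        mesh_id = lexicon.lookup(term)
        if mesh_id is not None:
            mesh_ids.add(mesh_id)
    hpo_ids: set[str] = set()
    for mesh_id in mesh_ids:
        hpo_ids |= mesh_to_hpo(mesh_id, ontology)
    genes: set[str] = set()
    for hpo_id in hpo_ids:
        genes |= genes_for_hpo(hpo_id, ontology)
    return AnnotatedTrial(
        trial_id=record.trial_id,
        mentions=list(mentions),
        mesh_ids=mesh_ids,
        hpo_ids=hpo_ids,
        genes=genes,
        intervention_types=list(record.intervention_types),
    )


def build_associations(annotated: list[AnnotatedTrial]) -> AssociationTable:
    """Aggregate annotated trials into the full association table.

    The result is independent of trial order: all cross-trial structures
    are sets or commutative counters keyed by ids.
    """
    table = AssociationTable()
    for trial in annotated:
        table.trial_mentions[trial.trial_id] = list(trial.mentions)
        table.trial_hpo[trial.trial_id] = set(trial.hpo_ids)
        table.trial_mesh[trial.trial_id] = set(trial.mesh_ids)
        table.total_mentions += len(trial.mentions)

        mention_counts: dict[str, int] = {}
        for mention in trial.mentions:
            mention_counts[mention.canonical] = mention_counts.get(mention.canonical, 0) + 1
            table.mutation_kind.setdefault(mention.canonical, mention.kind)
            table.mutation_trials.setdefault(mention.canonical, set()).add(trial.trial_id)
        for hpo_id in trial.hpo_ids:
            table.hpo_trials.setdefault(hpo_id, set()).add(trial.trial_id)
            for canonical, n in mention_counts.items():
                table.hpo_mutations.setdefault(hpo_id, set()).add(canonical)
                pair = table.mutation_hpo_counts.setdefault((canonical, hpo_id), PairCount())
                pair.trials += 1
                pair.mentions += n
    return table


def _round_pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage with banker's (half-even) rounding, as reported."""
    return round(100.0 * numerator / denominator, ndigits)


def intervention_breakdown(annotated: list[AnnotatedTrial]) -> dict[str, InterventionStats]:
    """Per intervention type: trial count and percent with genes/SNPs/proteins.

    A trial listing k distinct intervention types contributes to k rows; a
    type with zero trials produces no row.  Percentages are of trials in
    the row whose HPO nodes map to at least one gene, with at least one SNP
    mention, and with at least one protein mention respectively.
    """
    buckets: dict[str, list[AnnotatedTrial]] = {}
    for trial in annotated:
        for itype in sorted(set(trial.intervention_types)):
            buckets.setdefault(itype, []).append(trial)
    stats: dict[str, InterventionStats] = {}
    for itype in sorted(buckets):
        trials = buckets[itype]
        n = len(trials)
        stats[itype] = InterventionStats(
            n_trials=n,
            pct_gene_mapped=_round_pct(sum(1 for t in trials if t.genes), n),
            pct_rsid=_round_pct(sum(1 for t in trials if t.snp_canonicals), n),
            pct_protein=_round_pct(sum(1 for t in trials if t.protein_canonicals), n),
        )
    return stats


def condition_variant_groups(
    records: list[TrialRecord],
    ontology: Ontology,
    lexicon: MeshLexicon,
) -> dict[str, set[str]]:
    """Group free-form condition strings under normalized ontology nodes.

    Condition strings are matched case-/punctuation-insensitively against
    HPO names and synonyms, then against MeSH lexicon terms (resolved to
    HPO via xrefs, or kept under a ``MESH:<id>`` key when no xref exists).
    Exact/synonym matching only — no stemming or fuzzy distance.  Unmatched
    strings land under :data:`NO_MATCH`.
    """
    name_index = ontology.name_index()
    groups: dict[str, set[str]] = {}
    for record in records:
        for condition in record.conditions:
            key = normalize_label(condition)
            keys: list[str] = []
            if key in name_index:
                keys = [name_index[key]]
            else:
                mesh_id = lexicon.lookup(condition)
                if mesh_id is not None:
                    hpo_ids = mesh_to_hpo(mesh_id, ontology)
                    keys = sorted(hpo_ids) if hpo_ids else [f"MESH:{mesh_id}"]
            if not keys:
                keys = [NO_MATCH]
            for k in keys:
                groups.setdefault(k, set()).add(condition)
    return groups


# --- flat exports -------------------------------------------------------------

def write_association_tsvs(
    table: AssociationTable,
    stats: dict[str, InterventionStats],
    outdir: str | Path,
) -> list[Path]:
    """Write the flat TSV views (mutation_hpo, hpo_mutations, intervention_stats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    path = outdir / "mutation_hpo.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("canonical\thpo_id\ttrial_count\tmention_count\n")
        for (m, h), c in sorted(table.mutation_hpo_counts.items()):
            fh.write(f"{m}\t{h}\t{c.trials}\t{c.mentions}\n")
    paths.append(path)

    path = outdir / "hpo_mutations.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("hpo_id\tn_mutations\tmutations\n")
        for h, ms in sorted(table.hpo_mutations.items()):
            fh.write(f"{h}\t{len(ms)}\t{','.join(sorted(ms))}\n")
    paths.append(path)

    path = outdir / "intervention_stats.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("intervention_type\tn_trials\tpct_gene_mapped\tpct_rsid\tpct_protein\n")
        for itype, s in sorted(stats.items()):
            fh.write(
                f"{itype}\t{s.n_trials}\t{s.pct_gene_mapped}\t{s.pct_rsid}\t{s.pct_protein}\n"
            )
    paths.append(path)
    return paths
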