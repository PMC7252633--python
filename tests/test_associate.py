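"""MeSH->HPO normalization of trials and the counted association tables."""

import random

import pytest

from trialminer.associate import (
    NO_MATCH,
    annotate_trial,
    build_associations,
    condition_variant_groups,
    intervention_breakdown,
    write_association_tsvs,
)
from trialminer.corpus_io import TrialRecord
from trialminer.textmine import PROTEIN, SNP, MutationMention


def _mention(canonical, trial_id, kind=SNP, sentence="s"):
    return MutationMention(
        kind=kind, raw=canonical, canonical=canonical, sentence=sentence, trial_id=trial_id
    )


class TestAnnotateTrial:
    def test_mesh_chain_resolves_to_hpo_and_genes(self, ontology, lexicon):
        rec = TrialRecord(trial_id="NCT1", mesh_terms=["Multicystic Dysplastic Kidney"])
        ann = annotate_trial(rec, [], lexicon, ontology)
        assert ann.mesh_ids == {"D021782"}
        assert ann.hpo_ids == {"HP:0000003"}
        assert ann.genes == {"PAX2"}

    def test_no_mesh_tags(self, ontology, lexicon):
        ann = annotate_trial(TrialRecord(trial_id="NCT1"), [], lexicon, ontology)
        assert ann.hpo_ids == set() and ann.genes == set()

    def test_two_mesh_ids_same_node_deduplicate(self, ontology, lexicon):
        # both terms resolve, but only one maps onto an HPO node
        rec = TrialRecord(trial_id="NCT1", mesh_terms=["Asthma", "asthma"])
        ann = annotate_trial(rec, [], lexicon, ontology)
        assert ann.hpo_ids == {"HP:0002099"}

    def test_unresolvable_terms_dropped(self, ontology, lexicon):
        rec = TrialRecord(trial_id="NCT1", mesh_terms=["Not In Lexicon"])
        ann = annotate_trial(rec, [], lexicon, ontology)
        assert ann.mesh_ids == set()


class TestBuildAssociations:
    def _annotated(self, trial_id, canonicals, hpo_ids, kind=SNP):
        from trialminer.associate import AnnotatedTrial

        return AnnotatedTrial(
            trial_id=trial_id,
            mentions=[_mention(c, trial_id, kind) for c in canonicals],
            hpo_ids=set(hpo_ids),
        )

    def test_pair_counted_once_per_trial(self):
        table = build_associations(
            [
                self._annotated("NCT1", ["rs1"], ["HP:X"]),
                self._annotated("NCT2", ["rs1"], ["HP:X"]),
            ]
        )
        assert table.mutation_hpo_counts[("rs1", "HP:X")].trials == 2

    def test_mention_level_counts_repeats(self):
        table = build_associations([self._annotated("NCT1", ["rs1", "rs1"], ["HP:X"])])
        pair = table.mutation_hpo_counts[("rs1", "HP:X")]
        assert pair.trials == 1 and pair.mentions == 2

    def test_trial_with_mutations_but_no_hpo(self):
        table = build_associations([self._annotated("NCT1", ["rs1"], [])])
        assert table.mutation_trials["rs1"] == {"NCT1"}
        assert table.mutation_hpo_counts == {}

    def test_hpo_mutation_union_across_trials(self):
        table = build_associations(
            [
                self._annotated("NCT1", ["rs1", "rs2"], ["HP:X"]),
                self._annotated("NCT2", ["rs2", "rs3"], ["HP:X"]),
            ]
        )
        assert table.hpo_mutations["HP:X"] == {"rs1", "rs2", "rs3"}

    def test_conservation_of_mentions(self, result):
        total = sum(len(m) for m in result.mentions.values())
        assert result.assoc.total_mentions == total
        by_pair = {}
        for trial in result.annotated:
            for m in trial.mentions:
                by_pair[m.canonical] = by_pair.get(m.canonical, 0) + 1
        assert sum(by_pair.values()) == total

    def test_trial_counts_never_exceed_mention_counts(self, result):
        for pair in result.assoc.mutation_hpo_counts.values():
            assert pair.trials <= pair.mentions

    def test_order_independence(self, result):
        shuffled = list(result.annotated)
        random.Random(11).shuffle(shuffled)
        again = build_associations(shuffled)
        assert again.mutation_hpo_counts == result.assoc.mutation_hpo_counts
        assert again.hpo_mutations == result.assoc.hpo_mutations
        assert again.mutation_trials == result.assoc.mutation_trials

    def test_json_round_trip(self, result, tmp_path):
        from trialminer.associate import AssociationTable

        path = tmp_path / "assoc.json"
        result.assoc.write_json(path)
        again = AssociationTable.read_json(path)
        assert again.to_dict() == result.assoc.to_dict()


class TestInterventionBreakdown:
    def _trial(self, trial_id, itypes, canonicals=(), kind=SNP, genes=()):
        from trialminer.associate import AnnotatedTrial

        return AnnotatedTrial(
            trial_id=trial_id,
            mentions=[_mention(c, trial_id, kind) for c in canonicals],
            intervention_types=list(itypes),
            genes=set(genes),
        )

    def test_quarter_with_rsid(self):
        trials = [self._trial(f"NCT{i}", ["Genetic"]) for i in range(3)]
        trials.append(self._trial("NCT3", ["Genetic"], ["rs1"]))
        stats = intervention_breakdown(trials)
        assert stats["Genetic"].n_trials == 4
        assert stats["Genetic"].pct_rsid == 25.0

    def test_zero_trial_type_has_no_row(self):
        stats = intervention_breakdown([self._trial("NCT1", ["Drug"])])
        assert "Radiation" not in stats

    def test_multi_type_trial_counts_in_each_row(self):
        stats = intervention_breakdown([self._trial("NCT1", ["Drug", "Genetic"], ["T790M"], PROTEIN)])
        assert stats["Drug"].n_trials == 1 and stats["Genetic"].n_trials == 1
        assert stats["Drug"].pct_protein == 100.0

    def test_gene_mapped_percentage(self):
        trials = [
            self._trial("NCT1", ["Drug"], genes={"EGFR"}),
            self._trial("NCT2", ["Drug"]),
        ]
        assert intervention_breakdown(trials)["Drug"].pct_gene_mapped == 50.0


class TestConditionVariantGroups:
    SIX = [
        "Diabetes Mellitus, Type 1",
        "Type 1 Diabetes",
        "Type 1 Diabetes Mellitus",
        "Type1diabetes",
        "Type1 Diabetes Mellitus",
        "Diabetes Mellitus Type 1",
    ]

    def test_six_spellings_normalize_to_single_node(self, ontology, lexicon):
        records = [TrialRecord(trial_id=f"NCT{i}", conditions=[c]) for i, c in enumerate(self.SIX)]
        groups = condition_variant_groups(records, ontology, lexicon)
        assert groups["HP:0100651"] == set(self.SIX)
        assert NO_MATCH not in groups

    def test_exact_name_match(self, ontology, lexicon):
        records = [TrialRecord(trial_id="NCT1", conditions=["Asthma"])]
        groups = condition_variant_groups(records, ontology, lexicon)
        assert groups == {"HP:0002099": {"Asthma"}}

    def test_gibberish_goes_to_no_match_bucket(self, ontology, lexicon):
        records = [TrialRecord(trial_id="NCT1", conditions=["xqzzt flurble"])]
        groups = condition_variant_groups(records, ontology, lexicon)
        assert groups[NO_MATCH] == {"xqzzt flurble"}


def test_tsv_exports_written(result, tmp_path):
    stats = intervention_breakdown(result.annotated)
    paths = write_association_tsvs(result.assoc, stats, tmp_path)
    assert [p.name for p in paths] == ["mutation_hpo.tsv", "hpo_mutations.tsv", "intervention_stats.tsv"]
    header = paths[0].read_text().splitlines()[0]
    assert header == "canonical\thpo_id\ttrial_count\tmention_count"
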