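"""Incidence matrix construction, unit rows, cosine scores and rankings."""

import numpy as np
import pytest

from trialminer.associate import AnnotatedTrial, build_associations
from trialminer.similarity import (
    BOTH,
    EmptySelectionError,
    IncidenceMatrix,
    UnknownQueryError,
    build_incidence,
    pairwise_scores,
    related_terms,
    unit_rows,
    write_matrix_export,
)
from trialminer.synthcorpus import table_fixtures
from trialminer.textmine import PROTEIN, SNP, MutationMention


def _assoc(mapping, kind=SNP):
    """Build an association table from {hpo: [canonicals]} via tiny trials."""
    trials = []
    for i, (hpo, canonicals) in enumerate(sorted(mapping.items())):
        mentions = [
            MutationMention(kind=kind, raw=c, canonical=c, sentence="s", trial_id=f"NCT{i}")
            for c in canonicals
        ]
        trials.append(AnnotatedTrial(trial_id=f"NCT{i}", mentions=mentions, hpo_ids={hpo}))
    return build_associations(trials)


class TestBuildIncidence:
    def test_two_by_two(self):
        m = build_incidence(_assoc({"HP:A": ["s1", "s2"], "HP:B": ["s2"]}))
        assert m.row_labels == ["HP:A", "HP:B"]
        assert m.col_labels == ["s1", "s2"]
        assert m.cells.tolist() == [[1, 1], [0, 1]]

    def test_single_association(self):
        m = build_incidence(_assoc({"HP:A": ["s1"]}))
        assert m.shape == (1, 1) and m.cells.tolist() == [[1.0]]

    def test_both_merges_kinds_as_distinct_columns(self):
        snp = _assoc({"HP:A": ["rs1"]})
        prot = _assoc({"HP:A": ["T790M"]}, kind=PROTEIN)
        merged = build_associations(
            [
                AnnotatedTrial(
                    trial_id="NCT0",
                    mentions=snp.trial_mentions["NCT0"] + prot.trial_mentions["NCT0"],
                    hpo_ids={"HP:A"},
                )
            ]
        )
        m = build_incidence(merged, columns=BOTH)
        assert m.col_labels == ["T790M", "rs1"]

    def test_empty_selection_raises(self):
        with pytest.raises(EmptySelectionError):
            build_incidence(_assoc({"HP:A": ["rs1"]}), columns=PROTEIN)


class TestUnitRows:
    def test_two_ones_scale_to_inv_sqrt2(self):
        m = unit_rows(build_incidence(_assoc({"HP:A": ["s1", "s2"], "HP:B": ["s2"]})))
        assert np.allclose(m.units[0], [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_single_cell_row_stays_one(self):
        m = unit_rows(build_incidence(_assoc({"HP:A": ["s1"]})))
        assert m.units.tolist() == [[1.0]]

    def test_zero_row_flagged_not_fatal(self):
        m = IncidenceMatrix(row_labels=["HP:A", "HP:B"], col_labels=["s1"],
                            cells=np.array([[1.0], [0.0]]))
        unit_rows(m)
        assert m.zero_rows == ["HP:B"]
        assert m.units[1].tolist() == [0.0]


class TestPairwiseScores:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ({"HP:A": ["s1", "s2"], "HP:B": ["s1", "s2"]}, 1.0),  # identical support
            ({"HP:A": ["s1"], "HP:B": ["s2"]}, 0.0),  # disjoint
            ({"HP:A": ["s1", "s2"], "HP:B": ["s2", "s3"]}, 0.5),  # one shared of two each
        ],
    )
    def test_engineered_scores(self, rows, expected):
        scores = pairwise_scores(build_incidence(_assoc(rows)))
        assert scores[0, 1] == pytest.approx(expected)

    def test_identical_printed_rsid_profiles_score_one(self):
        """The two published behavioral-phenotype rsID panels are
        element-identical sets, so their binary profiles must score 1."""
        fx = table_fixtures()
        a, b = set(fx["table3_impulsivity"].ids), set(fx["table3_aggressive"].ids)
        assert a == b  # independent set-equality check of the printed lists
        scores = pairwise_scores(
            build_incidence(_assoc({"HP:0100710": sorted(a), "HP:0000718": sorted(b)}))
        )
        assert scores[0, 1] == pytest.approx(1.0)

    def test_symmetry_bounds_and_diagonal(self, result):
        m = build_incidence(result.assoc, columns=BOTH)
        scores = pairwise_scores(m)
        assert np.abs(scores - scores.T).max() <= 1e-12
        assert scores.min() >= 0.0 and scores.max() <= 1.0
        assert np.allclose(np.diag(scores), 1.0)

    def test_cauchy_schwarz_equality_iff_identical_support(self):
        m = build_incidence(_assoc({"HP:A": ["s1", "s2"], "HP:B": ["s1", "s2"], "HP:C": ["s1"]}))
        scores = pairwise_scores(m)
        assert scores[0, 1] == pytest.approx(1.0)
        assert scores[0, 2] < 1.0

    def test_matches_bruteforce_dot_product_on_random_matrices(self):
        """100 seeded random 10x10 binary matrices against a double loop."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cells = rng.integers(0, 2, size=(10, 10)).astype(float)
            m = IncidenceMatrix(
                row_labels=[f"HP:{i}" for i in range(10)],
                col_labels=[f"s{j}" for j in range(10)],
                cells=cells,
            )
            scores = pairwise_scores(m)
            units = m.units
            for i in range(10):
                for j in range(10):
                    brute = sum(units[i, k] * units[j, k] for k in range(10))
                    assert scores[i, j] == pytest.approx(min(brute, 1.0), abs=1e-12)

    def test_transpose_duality(self, result):
        m = build_incidence(result.assoc, columns=BOTH)
        direct = pairwise_scores(m.transpose())
        # clustering mutations by HPO profile == pipeline on the transpose
        swapped = IncidenceMatrix(
            row_labels=m.col_labels, col_labels=m.row_labels, cells=m.cells.T.copy()
        )
        assert np.allclose(direct, pairwise_scores(swapped))


class TestRelatedTerms:
    def test_ranking_order_and_tie_break(self):
        m = build_incidence(
            _assoc({"HP:Q": ["s1", "s2"], "HP:A": ["s1", "s2"], "HP:B": ["s9"], "HP:C": ["s1", "s2"]})
        )
        ranking = related_terms(m, "HP:Q")
        assert [r[0] for r in ranking.ranked] == ["HP:A", "HP:C", "HP:B"]
        assert ranking.ranked[0][1] == pytest.approx(1.0)

    def test_k_larger_than_m_returns_full_list(self):
        m = build_incidence(_assoc({"HP:A": ["s1"], "HP:B": ["s1"]}))
        assert len(related_terms(m, "HP:A", k=99).ranked) == 1

    def test_query_excluded(self):
        m = build_incidence(_assoc({"HP:A": ["s1"], "HP:B": ["s1"]}))
        assert all(r[0] != "HP:A" for r in related_terms(m, "HP:A").ranked)

    def test_unknown_query_names_the_id(self):
        m = build_incidence(_assoc({"HP:A": ["s1"]}))
        with pytest.raises(UnknownQueryError, match="HP:ZZ"):
            related_terms(m, "HP:ZZ")

    def test_zero_norm_query_flagged_empty(self):
        m = IncidenceMatrix(row_labels=["HP:A", "HP:B"], col_labels=["s1"],
                            cells=np.array([[0.0], [1.0]]))
        unit_rows(m)
        ranking = related_terms(m, "HP:A")
        assert ranking.zero_norm_query and ranking.ranked == []


def test_matrix_export_triplets(tmp_path):
    m = build_incidence(_assoc({"HP:A": ["s1", "s2"], "HP:B": ["s2"]}))
    paths = write_matrix_export(m, tmp_path)
    triplets = paths[0].read_text().splitlines()
    assert triplets[0] == "row\tcol\tvalue"
    assert len(triplets) == 1 + 3  # three nonzero cells
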