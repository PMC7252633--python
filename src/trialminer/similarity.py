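"""HPO-term similarity from mutation co-occurrence profiles.

Each HPO node is represented by the binary vector of mutations it
co-occurs with (through shared trials): a binary incidence matrix with m
HPO rows and n mutation columns.  Rows are scaled to unit vectors, and the
pairwise dot products — cosine similarities, since the data are
nonnegative — rank how alike two phenotype terms' mutation profiles are:
1 for identical support, 0 for disjoint.

Rows whose mutations were all filtered out (zero norm) are flagged and
excluded from rankings rather than producing NaN scores.  Transposing the
matrix clusters mutations by their phenotype profiles instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from trialminer.associate import AssociationTable
from trialminer.textmine import PROTEIN, SNP

#: column selections for build_incidence
BOTH = "BOTH"


class EmptySelectionError(ValueError):
    """No associations of the requested mutation kind exist."""


class UnknownQueryError(KeyError):
    """The query id is not a row label of the incidence matrix."""


@dataclass
class IncidenceMatrix:
    """Binary HPO x mutation incidence matrix with a unit-row view.

    ``cells[i, j]`` is 1 iff HPO node ``row_labels[i]`` co-occurs with
    mutation ``col_labels[j]``.  ``units`` (populated by :func:`unit_rows`)
    holds the row-normalized view; zero rows stay zero and are flagged.
    """

    row_labels: list[str]
    col_labels: list[str]
    cells: np.ndarray
    units: np.ndarray | None = None
    zero_rows: list[str] = field(default_factory=list)

    @property
    def row_norms(self) -> np.ndarray:
        return np.sqrt((self.cells.astype(float) ** 2).sum(axis=1))

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def transpose(self) -> "IncidenceMatrix":
        """Swap rows and columns (cluster mutations by HPO profile)."""
        return IncidenceMatrix(
            row_labels=list(self.col_labels),
            col_labels=list(self.row_labels),
            cells=self.cells.T.copy(),
        )


@dataclass
class SimilarityRanking:
    """Descending ranked list of terms related to one query row."""

    query: str
    ranked: list[tuple[str, float]]
    zero_norm_query: bool = False


def build_incidence(
    assoc: AssociationTable, columns: str = SNP, weighted: bool = False
) -> IncidenceMatrix:
    """Build the incidence matrix from an association table.

    Parameters
    ----------
    columns:
        ``"SNP"``, ``"PROTEIN"``, or ``"BOTH"``; selects which mutation
        canonicals become columns (merged as distinct columns for BOTH).
    weighted:
        When True, cells hold trial-level co-occurrence counts instead of
        binary presence.  Off by default: the similarity example is defined
        on presence.

    Rows are every HPO id associated with at least one selected mutation;
    row and column labels are sorted lexicographically for determinism.
    """
    columns = columns.upper()
    if columns == BOTH:
        selected = set(assoc.mutation_kind)
    elif columns in (SNP, PROTEIN):
        selected = assoc.mutations_of_kind(columns)
    else:
        raise ValueError(f"columns must be SNP, PROTEIN or BOTH, not {columns!r}")

    pairs = [
        (hpo, muts & selected)
        for hpo, muts in assoc.hpo_mutations.items()
        if muts & selected
    ]
    if not pairs:
        raise EmptySelectionError(f"no associations of requested kind: {columns}")

    row_labels = sorted(h for h, _ in pairs)
    col_labels = sorted(set().union(*(m for _, m in pairs)))
    col_index = {c: j for j, c in enumerate(col_labels)}
    cells = np.zeros((len(row_labels), len(col_labels)), dtype=float)
    by_hpo = dict(pairs)
    for i, hpo in enumerate(row_labels):
        for canonical in by_hpo[hpo]:
            if weighted:
                cells[i, col_index[canonical]] = assoc.mutation_hpo_counts[
                    (canonical, hpo)
                ].trials
            else:
                cells[i, col_index[canonical]] = 1.0
    return IncidenceMatrix(row_labels=row_labels, col_labels=col_labels, cells=cells)


def unit_rows(matrix: IncidenceMatrix) -> IncidenceMatrix:
    """Scale each nonzero row to unit magnitude; flag zero rows.

    Returns the same matrix object with its ``units`` view populated.
    """
    norms = matrix.row_norms
    units = np.zeros_like(matrix.cells, dtype=float)
    nonzero = norms > 0
    units[nonzero] = matrix.cells[nonzero] / norms[nonzero, None]
    matrix.units = units
    matrix.zero_rows = [lbl for lbl, nz in zip(matrix.row_labels, nonzero) if not nz]
    return matrix


def pairwise_scores(matrix: IncidenceMatrix) -> np.ndarray:
    """All pairwise dot products of the unit rows (m x m, symmetric).

    Scores lie in [0, 1]; the diagonal is 1 for nonzero rows.  Calls
    :func:`unit_rows` first if the unit view is missing.
    """
    if matrix.units is None:
        unit_rows(matrix)
    scores = matrix.units @ matrix.units.T
    return np.clip(scores, 0.0, 1.0)


def related_terms(matrix: IncidenceMatrix, query: str, k: int | None = None) -> SimilarityRanking:
    """Top-k rows most similar to ``query``, descending by cosine score.

    Ties break lexicographically by row label.  The query itself and
    zero-norm rows are excluded; a zero-norm query yields an empty,
    flagged ranking.
    """
    if query not in matrix.row_labels:
        raise UnknownQueryError(f"unknown query id: {query}")
    scores = pairwise_scores(matrix)
    qi = matrix.row_labels.index(query)
    if query in matrix.zero_rows:
        return SimilarityRanking(query=query, ranked=[], zero_norm_query=True)
    zero = set(matrix.zero_rows)
    candidates = [
        (label, float(scores[qi, i]))
        for i, label in enumerate(matrix.row_labels)
        if i != qi and label not in zero
    ]
    candidates.sort(key=lambda pair: (-pair[1], pair[0]))
    if k is not None:
        candidates = candidates[:k]
    return SimilarityRanking(query=query, ranked=candidates)


def write_matrix_export(matrix: IncidenceMatrix, outdir: str | Path) -> list[Path]:
    """Sparse triplet TSV (row, col, value) plus row/column label files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    path = outdir / "incidence_triplets.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row\tcol\tvalue\n")
        rows, cols = np.nonzero(matrix.cells)
        for i, j in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{matrix.row_labels[i]}\t{matrix.col_labels[j]}\t{matrix.cells[i, j]:g}\n")
    paths.append(path)
    for name, labels in (("row_labels.txt", matrix.row_labels), ("col_labels.txt", matrix.col_labels)):
        path = outdir / name
        path.write_text("\n".join(labels) + "\n", encoding="utf-8")
        paths.append(path)
    return paths
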