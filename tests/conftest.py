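"""Shared fixtures: one generated synthetic world per test session."""

from pathlib import Path

import pytest

from trialminer.corpus_io import load_mesh_lexicon
from trialminer.ontology import parse_annotations, parse_obo
from trialminer.pipeline import run_pipeline
from trialminer.synthcorpus import default_spec, generate


@pytest.fixture(scope="session")
def world(tmp_path_factory) -> dict:
    """Deterministic synthetic corpus + ontology + lexicon + manifest."""
    outdir = tmp_path_factory.mktemp("world")
    manifest = generate(default_spec(7, n_trials=12, decoys=4), outdir)
    return {
        "root": Path(outdir),
        "corpus": Path(outdir) / "corpus",
        "obo": Path(outdir) / "ontology.obo",
        "lexicon": Path(outdir) / "lexicon.tsv",
        "annotations": Path(outdir) / "annotations.tsv",
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def ontology(world):
    onto = parse_obo(world["obo"])
    return parse_annotations(world["annotations"], onto)


@pytest.fixture(scope="session")
def lexicon(world):
    return load_mesh_lexicon(world["lexicon"])


@pytest.fixture(scope="session")
def result(world):
    """Full pipeline run over the session world."""
    return run_pipeline(world["corpus"], world["obo"], world["annotations"], world["lexicon"])
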