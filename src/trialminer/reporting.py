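"""Static HTML reports and machine-readable JSON exports.

One page per unique mutation canonical (SNPs under ``snp/``, protein
mutations under ``mutation/``), one page per trial with at least one
mention (``trial/``), plus index pages — all static hyperlinked XHTML with
a single bundled stylesheet and no JavaScript.  Each mutation page lists
the trials it appears in with the containing sentences, the mapped HPO and
MeSH ids (hyperlinked to their browsers), and the genes annotated to each
HPO term.  A left-hand navigation column lists every mutation (or trial)
for quick crawling.

Output is organized by snapshot date (``site/<ISO-date>/...``) so repeated
runs over time coexist and can be diffed at the file level.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

from trialminer.associate import AssociationTable
from trialminer.ontology import Ontology, genes_for_hpo
from trialminer.similarity import IncidenceMatrix
from trialminer.textmine import PROTEIN, SNP

#: external URL templates, overridable by callers
URL_TEMPLATES = {
    "dbsnp": "https://www.ncbi.nlm.nih.gov/snp/{id}",
    "hpo": "https://hpo.jax.org/app/browse/term/{id}",
    "mesh": "https://meshb.nlm.nih.gov/record/ui?ui={id}",
}

_STYLESHEET = """\
body { font-family: sans-serif; margin: 0; display: flex; }
nav { width: 14em; padding: 1em; background: #f4f4f4; overflow-y: auto; }
main { padding: 1em 2em; flex: 1; }
nav ul { list-style: none; padding-left: 0; }
h1 { font-size: 1.4em; }
.sentence { margin: 0.2em 0 0.6em 1em; color: #333; }
"""


class UnknownEntityError(KeyError):
    """Requested canonical or trial id absent from the association table."""


@dataclass
class ReportBundle:
    """Manifest of one rendered snapshot: every page written, by category."""

    snapshot_label: str
    root: Path
    mutation_pages: list[Path] = field(default_factory=list)
    trial_pages: list[Path] = field(default_factory=list)
    index_pages: list[Path] = field(default_factory=list)
    api_files: list[Path] = field(default_factory=list)


def _esc(text: str) -> str:
    return html.escape(str(text), quote=True)


def _page(title: str, nav_title: str, nav_items: list[tuple[str, str]], body: str) -> str:
    """Assemble a complete XHTML page with sidebar navigation."""
    nav_links = "\n".join(
        f'<li><a href="{_esc(href)}">{_esc(label)}</a></li>' for label, href in nav_items
    )
    return (
        '<html xmlns="http://www.w3.org/1999/xhtml">\n'
        f"<head><title>{_esc(title)}</title>"
        '<link rel="stylesheet" href="../style.css" /></head>\n'
        "<body>\n"
        f"<nav><h2>{_esc(nav_title)}</h2><ul>\n{nav_links}\n</ul></nav>\n"
        f"<main>\n<h1>{_esc(title)}</h1>\n{body}\n</main>\n"
        "</body>\n</html>\n"
    )


def _mutation_dir(kind: str) -> str:
    return "snp" if kind == SNP else "mutation"


def _mutation_href(canonical: str, kind: str) -> str:
    return f"../{_mutation_dir(kind)}/{canonical}.html"


def _nav_mutations(assoc: AssociationTable) -> list[tuple[str, str]]:
    return [
        (canonical, _mutation_href(canonical, assoc.mutation_kind[canonical]))
        for canonical in sorted(assoc.mutation_trials)
    ]


def _trials_with_mentions(assoc: AssociationTable) -> list[str]:
    return sorted(t for t, ms in assoc.trial_mentions.items() if ms)


def render_mutation_report(
    canonical: str, assoc: AssociationTable, ontology: Ontology
) -> str:
    """One mutation's page: trials, sentences, HPO/MeSH links, genes.

    Raises :class:`UnknownEntityError` for a canonical absent from the
    association table.
    """
    if canonical not in assoc.mutation_trials:
        raise UnknownEntityError(f"unknown mutation canonical: {canonical}")
    kind = assoc.mutation_kind[canonical]
    parts: list[str] = [f"<p>Kind: {_esc(kind)}"]
    if kind == SNP:
        url = URL_TEMPLATES["dbsnp"].format(id=canonical)
        parts.append(f' — <a href="{_esc(url)}">dbSNP</a>')
    parts.append("</p>")

    hpo_ids: set[str] = set()
    for trial_id in sorted(assoc.mutation_trials[canonical]):
        parts.append(
            f'<h2>Trial <a href="../trial/{_esc(trial_id)}.html">{_esc(trial_id)}</a></h2>'
        )
        for mention in assoc.trial_mentions[trial_id]:
            if mention.canonical == canonical:
                parts.append(f'<p class="sentence">{_esc(mention.sentence)}</p>')
        mesh_links = ", ".join(
            f'<a href="{_esc(URL_TEMPLATES["mesh"].format(id=m))}">{_esc(m)}</a>'
            for m in sorted(assoc.trial_mesh.get(trial_id, set()))
        )
        parts.append(f"<p>MeSH ids: {mesh_links or 'none'}</p>")
        hpo_ids |= assoc.trial_hpo.get(trial_id, set())

    parts.append("<h2>Phenotypes</h2><ul>")
    for hpo_id in sorted(hpo_ids):
        url = URL_TEMPLATES["hpo"].format(id=hpo_id)
        genes = ", ".join(sorted(genes_for_hpo(hpo_id, ontology))) or "no annotated genes"
        parts.append(
            f'<li><a href="{_esc(url)}">{_esc(hpo_id)}</a> '
            f"{_esc(ontology.name_of(hpo_id))} — genes: {_esc(genes)}</li>"
        )
    parts.append("</ul>")
    return _page(canonical, "Mutations", _nav_mutations(assoc), "\n".join(parts))


def render_trial_report(trial_id: str, assoc: AssociationTable) -> str:
    """One trial's page: unique mutations with all mention sentences.

    A mutation mentioned twice appears once in the list with both
    sentences shown; the sidebar lists every trial with mentions.
    """
    if trial_id not in assoc.trial_mentions:
        raise UnknownEntityError(f"unknown trial id: {trial_id}")
    mentions = assoc.trial_mentions[trial_id]
    parts: list[str] = []
    by_canonical: dict[str, list[str]] = {}
    for mention in mentions:
        by_canonical.setdefault(mention.canonical, []).append(mention.sentence)
    for canonical in sorted(by_canonical):
        kind = assoc.mutation_kind[canonical]
        parts.append(
            f'<h2><a href="{_esc(_mutation_href(canonical, kind))}">{_esc(canonical)}</a>'
            f" ({_esc(kind)})</h2>"
        )
        for sentence in by_canonical[canonical]:
            parts.append(f'<p class="sentence">{_esc(sentence)}</p>')
    mesh_links = ", ".join(
        f'<a href="{_esc(URL_TEMPLATES["mesh"].format(id=m))}">{_esc(m)}</a>'
        for m in sorted(assoc.trial_mesh.get(trial_id, set()))
    )
    hpo_links = ", ".join(
        f'<a href="{_esc(URL_TEMPLATES["hpo"].format(id=h))}">{_esc(h)}</a>'
        for h in sorted(assoc.trial_hpo.get(trial_id, set()))
    )
    parts.append(f"<p>MeSH ids: {mesh_links or 'none'}</p>")
    parts.append(f"<p>HPO terms: {hpo_links or 'none'}</p>")
    nav = [(t, f"../trial/{t}.html") for t in _trials_with_mentions(assoc)]
    return _page(trial_id, "Trials", nav, "\n".join(parts))


def export_api_data(
    assoc: AssociationTable, matrix: IncidenceMatrix | None, outdir: str | Path
) -> list[Path]:
    """Write the machine-readable exports (six JSON files) under ``outdir``.

    Files: MeSH ids with their trials; HPO terms with their trials; rsIDs
    with their trials; protein mutations with their trials; and the
    mutation-*relevant* MeSH and HPO subsets (only ids occurring in trials
    that carry at least one mutation).  Serialization is deterministic
    (sorted keys, fixed indentation), so re-export is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mesh_trials: dict[str, list[str]] = {}
    for trial_id, mesh_ids in assoc.trial_mesh.items():
        for mesh_id in mesh_ids:
            mesh_trials.setdefault(mesh_id, []).append(trial_id)
    mutation_trial_ids = set().union(*assoc.mutation_trials.values()) if assoc.mutation_trials else set()

    payloads: dict[str, dict] = {
        "mesh_terms.json": {m: sorted(t) for m, t in mesh_trials.items()},
        "hpo_trials.json": {h: sorted(t) for h, t in assoc.hpo_trials.items()},
        "rsid_trials.json": {
            m: sorted(t)
            for m, t in assoc.mutation_trials.items()
            if assoc.mutation_kind[m] == SNP
        },
        "protein_mutation_trials.json": {
            m: sorted(t)
            for m, t in assoc.mutation_trials.items()
            if assoc.mutation_kind[m] == PROTEIN
        },
        "relevant_mesh.json": {
            m: sorted(set(t) & mutation_trial_ids)
            for m, t in mesh_trials.items()
            if set(t) & mutation_trial_ids
        },
        "relevant_hpo.json": {h: sorted(ms) for h, ms in assoc.hpo_mutations.items()},
    }
    paths = []
    for name, payload in payloads.items():
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        paths.append(path)
    return paths


def write_bundle(
    assoc: AssociationTable,
    ontology: Ontology,
    outdir: str | Path,
    snapshot_label: str,
    matrix: IncidenceMatrix | None = None,
) -> ReportBundle:
    """Render the full snapshot: all pages, indexes, stylesheet, API files."""
    root = Path(outdir) / snapshot_label
    bundle = ReportBundle(snapshot_label=snapshot_label, root=root)
    for sub in ("snp", "mutation", "trial", "api"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    (root / "style.css").write_text(_STYLESHEET, encoding="utf-8")

    for canonical in sorted(assoc.mutation_trials):
        kind = assoc.mutation_kind[canonical]
        path = root / _mutation_dir(kind) / f"{canonical}.html"
        path.write_text(render_mutation_report(canonical, assoc, ontology), encoding="utf-8")
        bundle.mutation_pages.append(path)

    for trial_id in _trials_with_mentions(assoc):
        path = root / "trial" / f"{trial_id}.html"
        path.write_text(render_trial_report(trial_id, assoc), encoding="utf-8")
        bundle.trial_pages.append(path)

    mutation_items = [
        (c, f"{_mutation_dir(assoc.mutation_kind[c])}/{c}.html")
        for c in sorted(assoc.mutation_trials)
    ]
    trial_items = [(t, f"trial/{t}.html") for t in _trials_with_mentions(assoc)]
    index = (
        '<html xmlns="http://www.w3.org/1999/xhtml">\n'
        f"<head><title>Snapshot {_esc(snapshot_label)}</title>"
        '<link rel="stylesheet" href="style.css" /></head>\n<body>\n<main>\n'
        f"<h1>Snapshot {_esc(snapshot_label)}</h1>\n<h2>Mutations</h2>\n<ul>\n"
        + "\n".join(f'<li><a href="{_esc(h)}">{_esc(l)}</a></li>' for l, h in mutation_items)
        + "\n</ul>\n<h2>Trials</h2>\n<ul>\n"
        + "\n".join(f'<li><a href="{_esc(h)}">{_esc(l)}</a></li>' for l, h in trial_items)
        + "\n</ul>\n</main>\n</body>\n</html>\n"
    )
    index_path = root / "index.html"
    index_path.write_text(index, encoding="utf-8")
    bundle.index_pages.append(index_path)

    bundle.api_files = export_api_data(assoc, matrix, root / "api")
    assoc.write_json(root / "associations.json")
    return bundle
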