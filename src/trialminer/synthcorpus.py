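"""Deterministic miniature corpus generator with planted ground truth.

``generate`` writes a complete offline test world — clinical-trial XML
files, a mini phenotype ontology in OBO format, a gene-annotation TSV and
a MeSH lexicon TSV — plus a JSON manifest enumerating every mutation
mention, MeSH id, HPO id and gene the pipeline is expected to recover.
Generation is a pure function of the :class:`PlantSpec` (same seed, same
bytes), so end-to-end tests can assert exact manifest recovery.

Planted mutations cycle through all six grammar surface forms (one-letter,
three-letter, and the four phrasal forms) embedded in clinical-trial style
sentences; decoy trials carry near-miss tokens and mutation-free prose.

``table_fixtures`` returns the published worked-example inputs — the
per-phenotype rsID and mutation lists and the breast-carcinoma validation
panel — as plain text with their printed counts, for extractor
benchmarking.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

from trialminer.textmine import AMINO_ACIDS

_ONE_TO_THREE = {one: three for one, three, _ in AMINO_ACIDS}
_ONE_TO_NAME = {one: names[0] for one, _, names in AMINO_ACIDS}
_CANONICAL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

#: the eleven registry intervention categories
INTERVENTION_TYPES = [
    "Behavioral", "Biological", "Combination Product", "Device",
    "Diagnostic Test", "Dietary Supplement", "Drug", "Genetic",
    "Other", "Procedure", "Radiation",
]

# --- mini ontology world (ground truth lives in these tables) ----------------

#: (hpo_id, name, synonyms, parents, xrefs, obsolete)
MINI_NODES: list[tuple[str, str, list[str], list[str], list[str], bool]] = [
    ("HP:0000001", "All", [], [], [], False),
    ("HP:0000077", "Abnormality of the kidney", [], ["HP:0000001"], ["MESH:D007674"], False),
    ("HP:0000107", "Renal cyst", [], ["HP:0000077"], ["MSH:D052177"], False),
    ("HP:0000003", "Multicystic kidney dysplasia", [], ["HP:0000107"],
     ["MSH:D021782", "SNOMEDCT_US:204962002", "SNOMEDCT_US:82525005", "UMLS:C3714581"], False),
    ("HP:0000819", "Diabetes mellitus", [], ["HP:0000001"], ["MSH:D003920"], False),
    ("HP:0100651", "Type I diabetes mellitus",
     ["Type 1 diabetes", "Type 1 diabetes mellitus", "Diabetes mellitus type 1",
      "Type1 diabetes mellitus", "Type1diabetes"],
     ["HP:0000819"], ["MSH:D003922", "UMLS:C0011854"], False),
    ("HP:0002099", "Asthma", [], ["HP:0000001"], ["MSH:D001249"], False),
    ("HP:0012115", "Hepatitis", [], ["HP:0000001"], ["MSH:D006505"], False),
    ("HP:0002664", "Neoplasm", ["Tumor"], ["HP:0000001"], ["MSH:D009369"], False),
    ("HP:0001909", "Leukemia", [], ["HP:0002664"], ["MSH:D007938"], False),
    ("HP:0003002", "Breast carcinoma", ["Breast cancer"], ["HP:0002664"], ["MSH:D001943"], False),
    ("HP:0100526", "Neoplasm of the lung", ["Lung cancer"], ["HP:0002664"], ["MSH:D008175"], False),
    ("HP:0030358", "Non-small cell lung carcinoma", [], ["HP:0100526"], ["MSH:D002289"], False),
    ("HP:0001513", "Obesity", [], ["HP:0000001"], ["MSH:D009765"], False),
    ("HP:0100710", "Impulsivity", [], ["HP:0000001"], ["SNOMEDCT_US:55542005"], False),
    ("HP:0099999", "Retired phenotype", [], [], ["MSH:D999999"], True),
]

#: MeSH lexicon rows (term, D-number); one term maps to no HPO node on purpose
MESH_LEXICON_ROWS: list[tuple[str, str]] = [
    ("Multicystic Dysplastic Kidney", "D021782"),
    ("Kidney Diseases", "D007674"),
    ("Polycystic Kidney Diseases", "D052177"),
    ("Diabetes Mellitus", "D003920"),
    ("Diabetes Mellitus, Type 1", "D003922"),
    ("Asthma", "D001249"),
    ("Hepatitis", "D006505"),
    ("Neoplasms", "D009369"),
    ("Leukemia", "D007938"),
    ("Breast Neoplasms", "D001943"),
    ("Lung Neoplasms", "D008175"),
    ("Carcinoma, Non-Small-Cell Lung", "D002289"),
    ("Obesity", "D009765"),
    ("Quality of Life", "D011788"),
]

#: gene annotation rows (ncbi_gene_id, gene_symbol, hpo_id)
ANNOTATION_ROWS: list[tuple[str, str, str]] = [
    ("1956", "EGFR", "HP:0030358"),
    ("1956", "EGFR", "HP:0100526"),
    ("7157", "TP53", "HP:0003002"),
    ("672", "BRCA1", "HP:0003002"),
    ("3630", "INS", "HP:0000819"),
    ("3630", "INS", "HP:0100651"),
    ("4893", "NRAS", "HP:0001909"),
    ("5079", "PAX2", "HP:0000003"),
    ("5310", "PKD1", "HP:0000107"),
]


def mini_obo_text() -> str:
    """Render :data:`MINI_NODES` as an OBO flat file."""
    lines = ["format-version: 1.2", "ontology: hp-mini", ""]
    for hpo_id, name, synonyms, parents, xrefs, obsolete in MINI_NODES:
        lines.append("[Term]")
        lines.append(f"id: {hpo_id}")
        lines.append(f"name: {name}")
        for syn in synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for xref in xrefs:
            lines.append(f"xref: {xref}")
        for parent in parents:
            lines.append(f"is_a: {parent}")
        if obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)


def mesh_lexicon_text() -> str:
    return "term\tmesh_id\n" + "".join(f"{t}\t{i}\n" for t, i in MESH_LEXICON_ROWS)


def annotations_text() -> str:
    lines = ["ncbi_gene_id\tgene_symbol\thpo_id\thpo_name"]
    names = {hid: name for hid, name, *_ in MINI_NODES}
    for ncbi, gene, hpo_id in ANNOTATION_ROWS:
        lines.append(f"{ncbi}\t{gene}\t{hpo_id}\t{names.get(hpo_id, '')}")
    return "\n".join(lines) + "\n"


def _ground_truth_mesh_to_hpo() -> dict[str, set[str]]:
    """Independent inversion of the mini ontology's MeSH xrefs."""
    index: dict[str, set[str]] = {}
    for hpo_id, _, _, _, xrefs, obsolete in MINI_NODES:
        if obsolete:
            continue
        for xref in xrefs:
            prefix, _, xid = xref.partition(":")
            if prefix in ("MSH", "MESH"):
                index.setdefault(xid, set()).add(hpo_id)
    return index


def _ground_truth_genes() -> dict[str, set[str]]:
    genes: dict[str, set[str]] = {}
    for _, gene, hpo_id in ANNOTATION_ROWS:
        genes.setdefault(hpo_id, set()).add(gene)
    return genes


# --- surface-form rendering ---------------------------------------------------

PROTEIN_FORMS = ("P1", "P2", "P3", "P4", "P5", "P6")


def render_surface(canonical: str, kind: str, form: str = "P1") -> str:
    """Write a canonical mutation in one of the grammar's surface forms."""
    if kind == "SNP":
        return canonical
    m = _CANONICAL_RE.match(canonical)
    if not m:
        raise ValueError(f"not a protein canonical: {canonical}")
    wt, pos, mt = m.groups()
    if form == "P1":
        return canonical
    if form == "P2":
        return f"{_ONE_TO_THREE[wt]}{pos}{_ONE_TO_THREE[mt]}"
    if form == "P3":
        return f"{_ONE_TO_NAME[wt]} to {_ONE_TO_NAME[mt]} at codon {pos}"
    if form == "P4":
        return f"{_ONE_TO_NAME[wt]}-to-{_ONE_TO_NAME[mt]} mutation at codon {pos}"
    if form == "P5":
        return f"{_ONE_TO_NAME[wt]} {pos} to {_ONE_TO_NAME[mt]}"
    if form == "P6":
        return f"{_ONE_TO_NAME[wt]} to {_ONE_TO_NAME[mt]} mutation at codon {pos}"
    raise ValueError(f"unknown surface form: {form}")


_SENTENCE_TEMPLATES = [
    "Patients carrying the {m} variant will be enrolled in this arm.",
    "This study evaluates treatment response in participants with {m}.",
    "Eligibility requires documented presence of {m} in tumor tissue.",
    "The association between {m} and clinical outcome is assessed.",
]

# vetted mutation-free filler (no rs+digits, no WT-pos-MT shapes)
_DECOY_SENTENCES = [
    "Participants versus controls will complete the questionnaire.",
    "The rs prefix alone never denotes a variant in this protocol.",
    "Cohort ABC will receive standard of care for twelve weeks.",
    "Samples labeled A123 and B456 are archival controls.",
    "Outcomes include quality of life and adherence measures.",
    "Dosing follows the approved schedule without modification.",
]


@dataclass
class PlantedTrial:
    """One synthetic trial: planted mutations, MeSH tags, intervention types."""

    trial_id: str
    mutations: list[tuple[str, str, str]] = field(default_factory=list)  # (canonical, kind, form)
    mesh_terms: list[str] = field(default_factory=list)
    intervention_types: list[str] = field(default_factory=list)


@dataclass
class PlantSpec:
    """Full recipe for one synthetic corpus; generation is pure in this."""

    seed: int
    n_trials: int
    planted: list[PlantedTrial] = field(default_factory=list)
    decoys: int = 0


_SNP_POOL = [
    "rs12979860", "rs9939609", "rs6971", "rs35652124", "rs1042713", "rs4680",
    "rs1800497", "rs7903146", "rs780094", "rs6280",
]
_PROTEIN_POOL = ["T790M", "L858R", "V600E", "T315I", "G12C", "H1047R", "E545K", "R132H"]


def default_spec(seed: int, n_trials: int = 12, decoys: int = 4) -> PlantSpec:
    """A realistic small study: mostly planted trials, a few decoys.

    Each planted trial carries one to three mutations (mixing SNPs and
    protein mutations), one to three MeSH tags drawn from the lexicon, and
    one or two intervention types.  Protein surface forms cycle through
    all six grammar patterns across the corpus.
    """
    if decoys > n_trials:
        raise ValueError("decoys cannot exceed n_trials")
    rng = random.Random(seed)
    planted: list[PlantedTrial] = []
    mesh_terms = [t for t, _ in MESH_LEXICON_ROWS]
    form_cycle = 0
    for i in range(n_trials - decoys):
        trial_id = f"NCT{seed % 1000:03d}{i:05d}"
        mutations: list[tuple[str, str, str]] = []
        for canonical in rng.sample(_SNP_POOL, rng.randint(0, 2)):
            mutations.append((canonical, "SNP", "P1"))
        for canonical in rng.sample(_PROTEIN_POOL, rng.randint(0, 2)):
            mutations.append((canonical, "PROTEIN", PROTEIN_FORMS[form_cycle % 6]))
            form_cycle += 1
        if not mutations:
            canonical = rng.choice(_SNP_POOL)
            mutations.append((canonical, "SNP", "P1"))
        planted.append(
            PlantedTrial(
                trial_id=trial_id,
                mutations=mutations,
                mesh_terms=rng.sample(mesh_terms, rng.randint(1, 3)),
                intervention_types=rng.sample(INTERVENTION_TYPES, rng.randint(1, 2)),
            )
        )
    return PlantSpec(seed=seed, n_trials=n_trials, planted=planted, decoys=decoys)


def _trial_xml(trial_id: str, title: str, summary_sentences: list[str],
               conditions: list[str], mesh_terms: list[str],
               intervention_types: list[str]) -> str:
    lines = ["<clinical_study>", "  <id_info>", f"    <nct_id>{trial_id}</nct_id>", "  </id_info>"]
    lines.append(f"  <brief_title>{title}</brief_title>")
    lines.append("  <brief_summary>")
    lines.append(f"    <textblock>{' '.join(summary_sentences)}</textblock>")
    lines.append("  </brief_summary>")
    lines.append("  <overall_status>Recruiting</overall_status>")
    lines.append("  <phase>Phase 2</phase>")
    lines.append("  <study_type>Interventional</study_type>")
    for cond in conditions:
        lines.append(f"  <condition>{cond}</condition>")
    for itype in intervention_types:
        lines.append("  <intervention>")
        lines.append(f"    <intervention_type>{itype}</intervention_type>")
        lines.append("    <intervention_name>Study treatment</intervention_name>")
        lines.append("  </intervention>")
    if mesh_terms:
        lines.append("  <condition_browse>")
        for term in mesh_terms:
            lines.append(f"    <mesh_term>{term}</mesh_term>")
        lines.append("  </condition_browse>")
    lines.append("</clinical_study>")
    return "\n".join(lines) + "\n"


def generate(spec: PlantSpec, outdir: str | Path) -> dict:
    """Write the synthetic world and return (and save) its truth manifest.

    Output layout::

        outdir/corpus/NCT*.xml    one trial per file
        outdir/ontology.obo       mini HPO with all xref prefix variants
        outdir/lexicon.tsv        MeSH term <-> id table
        outdir/annotations.tsv    gene annotations
        outdir/manifest.json      expected mentions, mappings, counts

    Raises ``ValueError`` on planted trial-id collisions.
    """
    ids = [t.trial_id for t in spec.planted]
    if len(ids) != len(set(ids)):
        raise ValueError("planted trial ids collide")

    outdir = Path(outdir)
    corpus_dir = outdir / "corpus"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    (outdir / "ontology.obo").write_text(mini_obo_text(), encoding="utf-8")
    (outdir / "lexicon.tsv").write_text(mesh_lexicon_text(), encoding="utf-8")
    (outdir / "annotations.tsv").write_text(annotations_text(), encoding="utf-8")

    rng = random.Random(spec.seed)
    lexicon = dict(MESH_LEXICON_ROWS)
    mesh_to_hpo = _ground_truth_mesh_to_hpo()
    hpo_genes = _ground_truth_genes()

    manifest: dict = {"seed": spec.seed, "trials": {}, "association": {}}
    mutation_trials: dict[str, set[str]] = {}
    hpo_mutations: dict[str, set[str]] = {}
    total_mentions = 0

    for trial in spec.planted:
        sentences = []
        expected = []
        for canonical, kind, form in trial.mutations:
            surface = render_surface(canonical, kind, form)
            template = rng.choice(_SENTENCE_TEMPLATES)
            sentences.append(template.format(m=surface))
            expected.append({"canonical": canonical, "kind": kind, "form": form})
        sentences.append(rng.choice(_DECOY_SENTENCES))
        mesh_ids = sorted({lexicon[t] for t in trial.mesh_terms})
        hpo_ids = sorted(set().union(*(mesh_to_hpo.get(m, set()) for m in mesh_ids)) if mesh_ids else set())
        genes = sorted(set().union(*(hpo_genes.get(h, set()) for h in hpo_ids)) if hpo_ids else set())
        xml = _trial_xml(
            trial.trial_id,
            title="A synthetic phase 2 study of targeted therapy.",
            summary_sentences=sentences,
            conditions=list(trial.mesh_terms),
            mesh_terms=list(trial.mesh_terms),
            intervention_types=list(trial.intervention_types),
        )
        (corpus_dir / f"{trial.trial_id}.xml").write_text(xml, encoding="utf-8")
        manifest["trials"][trial.trial_id] = {
            "mentions": expected,
            "mesh_ids": mesh_ids,
            "hpo_ids": hpo_ids,
            "genes": genes,
            "intervention_types": sorted(set(trial.intervention_types)),
        }
        total_mentions += len(expected)
        for canonical, _, _ in trial.mutations:
            mutation_trials.setdefault(canonical, set()).add(trial.trial_id)
            for h in hpo_ids:
                hpo_mutations.setdefault(h, set()).add(canonical)

    for d in range(spec.decoys):
        trial_id = f"NCTD{spec.seed % 1000:03d}{d:04d}"
        sentences = rng.sample(_DECOY_SENTENCES, 3)
        itypes = [rng.choice(INTERVENTION_TYPES)]
        xml = _trial_xml(
            trial_id,
            title="An observational study of standard care.",
            summary_sentences=sentences,
            conditions=["General wellbeing"],
            mesh_terms=["Quality of Life"],
            intervention_types=itypes,
        )
        (corpus_dir / f"{trial_id}.xml").write_text(xml, encoding="utf-8")
        manifest["trials"][trial_id] = {
            "mentions": [],
            "mesh_ids": ["D011788"],
            "hpo_ids": [],
            "genes": [],
            "intervention_types": sorted(set(itypes)),
        }

    manifest["association"] = {
        "mutation_trials": {m: sorted(t) for m, t in sorted(mutation_trials.items())},
        "hpo_mutations": {h: sorted(m) for h, m in sorted(hpo_mutations.items())},
        "total_mentions": total_mentions,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


# --- published worked-example fixtures ---------------------------------------

@dataclass
class TableFixture:
    """A published id list: raw comma-joined text plus its printed count."""

    name: str
    text: str
    ids: tuple[str, ...]
    printed_count: int


_TABLE3_IMPULSIVITY = (
    "rs1042713,rs1079598,rs1150226,rs1549339,rs16111115,rs1672717,rs1800497,"
    "rs1800955,rs1801253,rs2242447,rs2278392,rs2550946,rs4532,rs4680,rs4994,"
    "rs518147,rs553668,rs5569,rs6269,rs6280,rs6295,rs6296,rs6311"
)

_TABLE3_ASTHMA = (
    "rs1042711,rs1042713,rs1042714,rs1042718,rs11958940,rs11959427,rs12654778,"
    "rs12936231,rs1504982,rs17778257,rs1800888,rs1801275,rs1805010,rs2053044,"
    "rs2895795,rs324011,rs324015,rs4950928"
)

_TABLE3_LEUKEMIA = (
    "rs10509681,rs11572080,rs12459419,rs172378,rs2032582,rs230561,rs25531,"
    "rs3816527,rs396991,rs4880,rs4958351,rs6190,rs628031,rs776746,rs904627"
)

_TABLE6_NEOPLASM = (
    "C10D,C377T,C677T,C797S,D816V,D835V,D842V,E10A,E17K,E542K,E545K,F1174L,"
    "F31I,G12C,G12D,G12V,G13D,G156A,G20210A,G719A,G719C,H1047R,H1112L,H1112Y,"
    "H1124D,K652E,L1213V,L265P,L858R,L861Q,M1149T,M1268T,P1009S,P13K,P1446A,"
    "P286R,P4503A,Q12H,Q21D,R132C,R132G,R132H,R132L,R132S,R132V,R140L,R140Q,"
    "R140W,R172G,R172K,R172M,R172S,R172W,R988C,T1010I,T1191I,T315I,T790M,"
    "V1110L,V1206L,V1238I,V411L,V57I,V600D,V600E,V600K,V600M,V600R,V617F,"
    "V941L,Y1248C,Y1248D,Y1248H,Y1253D,Y842C"
)

_TABLE6_BREAST = (
    "A289T,A864V,C3435T,D538G,D769H,D769N,D769Y,D988Y,E380Q,E542K,E545K,E709K,"
    "E757A,G309A,G309E,G598V,G776C,G776V,H1047R,I655V,I767M,L536H,L536P,L536Q,"
    "L536R,L755P,L755S,L786V,L841V,L858R,L861Q,L869R,P125A,P12A,P13K,P187S,"
    "P535H,P596L,R108K,R222C,R572Y,R678Q,R831C,R831H,R849W,R896C,S310F,S310Y,"
    "S463P,S653C,S768I,S8814A,S9313A,T47D,T733I,T790M,T798I,T798M,T862I,V244M,"
    "V534E,V600E,V659E,V697L,V742I,V769M,V773M,V774M,V777L,V842I,Y537C,Y537N,"
    "Y537S"
)

_VALIDATION_BREAST = (
    "rs1011970, rs10407022, rs1045485, rs10941679, rs10995190, rs11045585, "
    "rs11133360, rs11249433, rs12762549, rs13281615, rs13387042, rs16942, "
    "rs1800566, rs2002555, rs2046210, rs2237060, rs2241193, rs2297480, "
    "rs236114, rs2380205, rs271924, rs2981582, rs3803662, rs3817198, rs4073, "
    "rs4646, rs4973768, rs614367, rs6504950, rs704010, rs7333181, rs7349683, "
    "rs889312, rs909253, rs9344, rs9457827, and rs999737"
)

_TABLE3_AGGRESSIVE = _TABLE3_IMPULSIVITY  # printed as element-identical lists


def table_fixtures() -> dict[str, TableFixture]:
    """Published id lists keyed by fixture name, with printed counts."""
    def make(name: str, text: str, count: int) -> TableFixture:
        ids = tuple(
            t for t in re.split(r"[,\s]+", text.replace(" and ", " ")) if t
        )
        return TableFixture(name=name, text=text, ids=ids, printed_count=count)

    return {
        "table3_impulsivity": make("table3_impulsivity", _TABLE3_IMPULSIVITY, 23),
        "table3_aggressive": make("table3_aggressive", _TABLE3_AGGRESSIVE, 23),
        "table3_asthma": make("table3_asthma", _TABLE3_ASTHMA, 18),
        "table3_leukemia": make("table3_leukemia", _TABLE3_LEUKEMIA, 15),
        "table6_neoplasm": make("table6_neoplasm", _TABLE6_NEOPLASM, 75),
        "table6_breast": make("table6_breast", _TABLE6_BREAST, 73),
        "validation_breast": make("validation_breast", _VALIDATION_BREAST, 37),
    }
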