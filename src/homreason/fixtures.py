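"""Demonstration and randomized fixtures.

:func:`build_demo` regenerates the fin/limb demonstration ontology — a small
anatomy graph (paired fins, limbs, their buds, parts, and developmental
relations), a vertebrate taxonomy, eleven curated homology assertions (two of
them negative), twenty-three entity–quality phenotype annotations, and the
expected answer sets for the seven competency questions under each homology
model.  :func:`build_random` emits seeded random fixtures of the same shape
for property testing.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assertions import (
    HomologyAssertion,
    parse_assertions,
    serialize_assertions,
)
from .ontograph import OntologyGraph, load_ontology
from .reasoner import PhenotypeAnnotation

ANATOMY_ROOT = "UBERON:demo:anatomical_structure"

# (id, label); ids printed in the source tables are kept, others get demo ids.
_ANATOMY_TERMS = [
    (ANATOMY_ROOT, "anatomical structure"),
    ("UBERON:demo:paired_fin", "paired fin"),
    ("UBERON:0000151", "pectoral fin"),
    ("UBERON:0000152", "pelvic fin"),
    ("UBERON:4200003", "archipterygial fin"),
    ("UBERON:demo:limb", "limb"),
    ("UBERON:0002102", "forelimb"),
    ("UBERON:0002103", "hindlimb"),
    ("UBERON:0000024", "forelimb wing"),
    ("UBERON:4300239", "hind flipper"),
    ("UBERON:demo:paired_fin_bud", "paired fin bud"),
    ("UBERON:4300172", "pectoral fin bud"),
    ("UBERON:demo:pelvic_fin_bud", "pelvic fin bud"),
    ("UBERON:demo:limb_bud", "limb bud"),
    ("UBERON:0005417", "forelimb bud"),
    ("UBERON:0005418", "hindlimb bud"),
    ("UBERON:4300230", "forelimb wing bud"),
    ("UBERON:0000976", "humerus"),
    ("UBERON:0000981", "femur"),
    ("UBERON:demo:pectoral_fin_ray", "pectoral fin ray"),
    ("UBERON:demo:forelimb_bud_mesenchyme", "forelimb bud mesenchyme"),
    ("UBERON:0003631", "pedal digit 1"),
    ("UBERON:0012136", "prehallux"),
    ("UBERON:demo:manual_digit_1", "manual digit 1"),
    ("UBERON:demo:manus", "manus"),
    ("UBERON:demo:phalanx", "phalanx"),
    ("UBERON:demo:pedal_digit_2", "pedal digit 2"),
    ("UBERON:demo:trunk_vertebra", "trunk vertebra"),
    ("UBERON:demo:cleithrum", "cleithrum"),
    ("UBERON:demo:posterior_region_of_body", "posterior region of body"),
]

_A = {label: tid for tid, label in _ANATOMY_TERMS}

_ANATOMY_ISA = [
    ("pectoral fin", "paired fin"),
    ("pelvic fin", "paired fin"),
    ("archipterygial fin", "pectoral fin"),
    ("forelimb", "limb"),
    ("hindlimb", "limb"),
    ("forelimb wing", "forelimb"),
    ("hind flipper", "hindlimb"),
    ("pectoral fin bud", "paired fin bud"),
    ("pelvic fin bud", "paired fin bud"),
    ("forelimb bud", "limb bud"),
    ("hindlimb bud", "limb bud"),
    ("forelimb wing bud", "forelimb bud"),
    # root attachments keep every term connected (as a real anatomy ontology does)
    ("paired fin", "anatomical structure"),
    ("limb", "anatomical structure"),
    ("paired fin bud", "anatomical structure"),
    ("limb bud", "anatomical structure"),
    ("humerus", "anatomical structure"),
    ("femur", "anatomical structure"),
    ("pectoral fin ray", "anatomical structure"),
    ("forelimb bud mesenchyme", "anatomical structure"),
    ("pedal digit 1", "anatomical structure"),
    ("prehallux", "anatomical structure"),
    ("manual digit 1", "anatomical structure"),
    ("manus", "anatomical structure"),
    ("phalanx", "anatomical structure"),
    ("pedal digit 2", "anatomical structure"),
    ("trunk vertebra", "anatomical structure"),
    ("cleithrum", "anatomical structure"),
    ("posterior region of body", "anatomical structure"),
]

_ANATOMY_PART_OF = [
    ("humerus", "forelimb"),
    ("femur", "hindlimb"),
    ("pectoral fin ray", "pectoral fin"),
    ("forelimb bud mesenchyme", "forelimb bud"),
    ("pedal digit 1", "hindlimb"),
    ("manual digit 1", "forelimb"),
    ("manus", "forelimb"),
    ("phalanx", "manus"),
]

_ANATOMY_DEVELOPS_FROM = [
    ("forelimb", "forelimb bud"),
    ("forelimb wing", "forelimb wing bud"),
    ("hindlimb", "hindlimb bud"),
    ("pectoral fin", "pectoral fin bud"),
    ("pelvic fin", "pelvic fin bud"),
]

# Uberon-style homology grouping classes (optional overlay, off by default).
_GROUPING_TERMS = [
    ("UBERON:0004708", "paired limb/fin"),
    ("UBERON:000435", "paired limb/fin bud"),
    ("UBERON:0004710", "pectoral appendage"),
    ("UBERON:000470", "pelvic appendage"),
]

_GROUPING_ISA = [
    ("paired limb/fin", "anatomical structure"),
    ("paired limb/fin bud", "anatomical structure"),
    ("pectoral appendage", "paired limb/fin"),
    ("pelvic appendage", "paired limb/fin"),
    ("paired fin", "paired limb/fin"),
    ("limb", "paired limb/fin"),
    ("paired fin bud", "paired limb/fin bud"),
    ("limb bud", "paired limb/fin bud"),
    ("pectoral fin", "pectoral appendage"),
    ("forelimb", "pectoral appendage"),
    ("pelvic fin", "pelvic appendage"),
    ("hindlimb", "pelvic appendage"),
]

# (id-suffix, label, parent label); species names get deterministic demo ids.
_TAXONOMY = [
    ("Vertebrata", "Vertebrata", None),
    ("Actinopterygii", "Actinopterygii", "Vertebrata"),
    ("Sarcopterygii", "Sarcopterygii", "Vertebrata"),
    ("Glyptolepis", "Glyptolepis", "Sarcopterygii"),
    ("Tetrapoda", "Tetrapoda", "Sarcopterygii"),
    ("Amphibia", "Amphibia", "Tetrapoda"),
    ("Mammalia", "Mammalia", "Tetrapoda"),
    ("Aves_lineage", "Aves lineage", "Tetrapoda"),
    ("Acanthostega_gunnari", "Acanthostega gunnari", "Tetrapoda"),
    ("Eoraptor_lunensis", "Eoraptor lunensis", "Tetrapoda"),
    ("Dicynodontia", "Dicynodontia", "Tetrapoda"),
    ("Anura", "Anura", "Amphibia"),
    ("Triadobatrachus_massinoti", "Triadobatrachus massinoti", "Amphibia"),
    ("Callobatrachus_sanyanensis", "Callobatrachus sanyanensis", "Anura"),
    ("Xenophrys_aceras", "Xenophrys aceras", "Anura"),
    ("Myotis_lucifugus", "Myotis lucifugus", "Mammalia"),
    ("Callorhinus_ursinus", "Callorhinus ursinus", "Mammalia"),
    ("Pteropus_giganteus", "Pteropus giganteus", "Mammalia"),
    ("Mus_musculus", "Mus musculus", "Mammalia"),
    ("Hippopotamus_amphibius", "Hippopotamus amphibius", "Mammalia"),
    ("Dasypus_novemcinctus", "Dasypus novemcinctus", "Mammalia"),
    ("Gallus_gallus_domesticus", "Gallus gallus domesticus", "Aves_lineage"),
    ("Danio_rerio", "Danio rerio", "Actinopterygii"),
    ("Acestrorhynchus_pantaneiro", "Acestrorhynchus pantaneiro", "Actinopterygii"),
    ("Colossoma_macropomum", "Colossoma macropomum", "Actinopterygii"),
    ("Adrianichthys_oophorus", "Adrianichthys oophorus", "Actinopterygii"),
]


def _vto(suffix: str) -> str:
    return f"VTO:demo:{suffix}"


# Curated assertion rows: (entity1, taxon1, relationship, entity2, taxon2,
# evidence ECO ids, attribution).
_ASSERTION_ROWS = [
    ("forelimb", "Tetrapoda", "serially_homologous_to", "hindlimb", "Tetrapoda",
     "ECO:0000060", "B63"),
    ("forelimb bud", "Tetrapoda", "serially_homologous_to", "hindlimb bud",
     "Tetrapoda", "ECO:0000075", "B69;B29"),
    ("humerus", "Tetrapoda", "serially_homologous_to", "femur", "Tetrapoda",
     "ECO:0000075", "B49"),
    ("pectoral fin", "Vertebrata", "homologous_to", "forelimb", "Tetrapoda",
     "ECO:0000034", "B23"),
    ("pectoral fin", "Vertebrata", "serially_homologous_to", "pelvic fin",
     "Vertebrata", "ECO:0000075", "B69;B29"),
    ("pectoral fin bud", "Vertebrata", "homologous_to", "forelimb bud",
     "Tetrapoda", "ECO:0000067", "B19;B29"),
    ("pelvic fin bud", "Vertebrata", "homologous_to", "hindlimb bud",
     "Tetrapoda", "ECO:0000067", "B19;B29"),
    ("pelvic fin", "Vertebrata", "homologous_to", "hindlimb", "Tetrapoda",
     "ECO:0000034", "B23"),
    ("prehallux", "Anura", "homologous_to", "pedal digit 1", "Tetrapoda",
     "ECO:0000067", "B20"),
    ("prehallux", "Anura", "not_homologous_to", "pedal digit 1", "Tetrapoda",
     "ECO:0000067", "B16"),
    ("prehallux", "Anura", "not_homologous_to", "pedal digit 1", "Tetrapoda",
     "ECO:0000067", "B20"),
]

# (entity label, quality, related entity label or None, taxon suffix)
_ANNOTATION_ROWS = [
    ("archipterygial fin", "present", None, "Glyptolepis"),
    ("forelimb", "length", "hindlimb", "Eoraptor_lunensis"),
    ("forelimb bud", "small", None, "Mus_musculus"),
    ("forelimb bud mesenchyme", "present", None, "Mus_musculus"),
    ("forelimb wing", "structure", None, "Pteropus_giganteus"),
    ("forelimb wing bud", "present", None, "Gallus_gallus_domesticus"),
    ("hind flipper", "present", None, "Callorhinus_ursinus"),
    ("hindlimb", "decreased length", None, "Triadobatrachus_massinoti"),
    ("humerus", "decreased length", "trunk vertebra", "Acanthostega_gunnari"),
    ("limb", "decreased length", None, "Dicynodontia"),
    ("manual digit 1", "torsioned", None, "Xenophrys_aceras"),
    ("manus", "has extra parts of type", "phalanx", "Hippopotamus_amphibius"),
    ("paired fin bud", "hypoplastic", None, "Danio_rerio"),
    ("pectoral fin", "position", "cleithrum", "Acestrorhynchus_pantaneiro"),
    ("pectoral fin bud", "aplastic", None, "Danio_rerio"),
    ("pectoral fin ray", "bifurcated", None, "Colossoma_macropomum"),
    ("pedal digit 1", "decreased length", "pedal digit 2", "Dasypus_novemcinctus"),
    ("pelvic fin", "located in", "posterior region of body",
     "Adrianichthys_oophorus"),
    ("prehallux", "present", None, "Myotis_lucifugus"),
    ("prehallux", "present", None, "Callobatrachus_sanyanensis"),
    # pre- vs post-composed near-duplicates are kept as distinct annotations
    ("forelimb bud", "small forelimb buds", None, "Mus_musculus"),
    ("hindlimb bud", "small hindlimb buds", None, "Mus_musculus"),
    ("limb bud", "small limb buds", None, "Mus_musculus"),
]


def _labels_to_ids(labels: Sequence[str]) -> list[str]:
    return sorted(_A[label] for label in labels)


def _expectations() -> dict:
    """Expected answer sets per competency question and model."""

    def cq(query, kind, expectation, rea, ava, rea_ann=None, ava_ann=None):
        d = {
            "query_entity": _A[query],
            "kind": kind,
            "expectation": _labels_to_ids(expectation),
            "rea": _labels_to_ids(rea),
            "ava": _labels_to_ids(ava),
        }
        if rea_ann is not None:
            d["rea_annotations"] = sorted(rea_ann)
            d["ava_annotations"] = sorted(ava_ann)
        return d

    prehallux_anuran = f"{_A['prehallux']}@{_vto('Callobatrachus_sanyanensis')}"
    pedal1_armadillo = f"{_A['pedal digit 1']}@{_vto('Dasypus_novemcinctus')}"
    return {
        "CQ1": cq("pectoral fin", "historical",
                  ["forelimb", "forelimb wing"],
                  ["forelimb", "forelimb wing"],
                  ["forelimb", "forelimb wing", "pectoral fin",
                   "archipterygial fin"]),
        "CQ2": cq("forelimb wing", "historical",
                  ["forelimb", "pectoral fin", "archipterygial fin"],
                  [],
                  ["forelimb", "pectoral fin", "archipterygial fin",
                   "forelimb wing"]),
        "CQ3": cq("pectoral fin bud", "historical",
                  ["forelimb bud", "forelimb wing bud"],
                  ["forelimb bud", "forelimb wing bud"],
                  ["forelimb bud", "forelimb wing bud", "pectoral fin bud"]),
        "CQ4": cq("pedal digit 1", "historical",
                  ["prehallux"],
                  ["prehallux"],
                  ["prehallux", "pedal digit 1"],
                  rea_ann=[prehallux_anuran],
                  ava_ann=[prehallux_anuran, pedal1_armadillo]),
        "CQ5": cq("hindlimb", "serial",
                  ["forelimb", "forelimb wing"],
                  ["forelimb", "forelimb wing"],
                  ["forelimb", "forelimb wing", "hindlimb", "hind flipper"]),
        "CQ6": cq("hindlimb bud", "serial",
                  ["forelimb bud", "forelimb wing bud"],
                  ["forelimb bud", "forelimb wing bud"],
                  ["forelimb bud", "forelimb wing bud", "hindlimb bud"]),
        "CQ7": cq("hind flipper", "serial",
                  ["forelimb", "forelimb wing"],
                  [],
                  ["forelimb", "forelimb wing", "hindlimb", "hind flipper"]),
    }


@dataclass
class DemoFixture:
    anatomy: OntologyGraph
    taxonomy: OntologyGraph
    assertions: list[HomologyAssertion]
    annotations: list[PhenotypeAnnotation]
    expectations: dict = field(default_factory=dict)
    scenario_extras: list[HomologyAssertion] = field(default_factory=list)
    scenario_expectations: dict = field(default_factory=dict)


def _build_anatomy(include_grouping_overlay: bool = False) -> OntologyGraph:
    terms = list(_ANATOMY_TERMS)
    label_to_id = dict(_A)
    isa = list(_ANATOMY_ISA)
    if include_grouping_overlay:
        terms += _GROUPING_TERMS
        label_to_id.update({label: tid for tid, label in _GROUPING_TERMS})
        isa = [e for e in isa if e not in
               [("paired fin", "anatomical structure"),
                ("limb", "anatomical structure"),
                ("paired fin bud", "anatomical structure"),
                ("limb bud", "anatomical structure")]]
        isa += _GROUPING_ISA
    term_rows = [
        {"id": tid, "label": label, "namespace": "anatomy"} for tid, label in terms
    ]
    edge_rows = [
        {"child_id": label_to_id[c], "relation": "is_a",
         "parent_id": label_to_id[p]}
        for c, p in isa
    ]
    edge_rows += [
        {"child_id": label_to_id[c], "relation": "part_of",
         "parent_id": label_to_id[p]}
        for c, p in _ANATOMY_PART_OF
    ]
    edge_rows += [
        {"child_id": label_to_id[c], "relation": "develops_from",
         "parent_id": label_to_id[p]}
        for c, p in _ANATOMY_DEVELOPS_FROM
    ]
    return load_ontology(term_rows, edge_rows)


def _build_taxonomy() -> OntologyGraph:
    term_rows = [
        {"id": _vto(sfx), "label": label, "namespace": "taxonomy"}
        for sfx, label, _ in _TAXONOMY
    ]
    edge_rows = [
        {"child_id": _vto(sfx), "relation": "is_a", "parent_id": _vto(parent)}
        for sfx, _, parent in _TAXONOMY
        if parent is not None
    ]
    return load_ontology(term_rows, edge_rows)


def build_demo(include_grouping_overlay: bool = False) -> DemoFixture:
    """Deterministically regenerate the fin/limb demonstration fixture."""
    anatomy = _build_anatomy(include_grouping_overlay)
    taxonomy = _build_taxonomy()
    assertion_rows = [
        {
            "entity1_id": _A[e1],
            "taxon1_id": _vto(t1),
            "relationship": rel,
            "entity2_id": _A[e2],
            "taxon2_id": _vto(t2),
            "evidence_eco_ids": ev,
            "attribution": att,
        }
        for e1, t1, rel, e2, t2, ev, att in _ASSERTION_ROWS
    ]
    assertions = parse_assertions(assertion_rows, anatomy, taxonomy)
    annotations = [
        PhenotypeAnnotation(
            entity=anatomy.term(_A[entity]),
            quality=quality,
            related_entity=anatomy.term(_A[rel]) if rel else None,
            organism_taxon=taxonomy.term(_vto(taxon)),
            source="KB",
        )
        for entity, quality, rel, taxon in _ANNOTATION_ROWS
    ]
    return DemoFixture(
        anatomy=anatomy,
        taxonomy=taxonomy,
        assertions=assertions,
        annotations=annotations,
        expectations=_expectations(),
    )


def build_general_scenario(include_grouping_overlay: bool = False) -> DemoFixture:
    """Demo fixture plus the over-general 'paired fin homologous to limb' row.

    Under AVA such a general assertion bleeds across the fin/limb split: a
    query for homologs of the pectoral fin now returns hindlimb phenotypes.
    Under REA the query answer is unchanged.
    """
    fx = build_demo(include_grouping_overlay)
    extra_rows = [
        {
            "entity1_id": _A["paired fin"],
            "taxon1_id": _vto("Vertebrata"),
            "relationship": "homologous_to",
            "entity2_id": _A["limb"],
            "taxon2_id": _vto("Tetrapoda"),
            "evidence_eco_ids": "ECO:0000034",
            "attribution": "B29",
        }
    ]
    extras = parse_assertions(extra_rows, fx.anatomy, fx.taxonomy)
    fx.scenario_extras = extras
    fx.assertions = fx.assertions + extras
    fx.scenario_expectations = {
        "query_entity": _A["pectoral fin"],
        "kind": "historical",
        "rea_exact": _labels_to_ids(["forelimb", "forelimb wing"]),
        "ava_must_include": _labels_to_ids(["hindlimb", "hind flipper"]),
    }
    return fx


# ---------------------------------------------------------------------------
# Fixture directory I/O (canonical inputs for the CLI)
# ---------------------------------------------------------------------------

def write_fixture(fx: DemoFixture, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    term_rows = [
        {"id": t.id, "label": t.label, "namespace": t.namespace}
        for g in (fx.anatomy, fx.taxonomy)
        for t in g.terms.values()
    ]
    edge_rows = [
        {"child_id": e.child.id, "relation": e.relation, "parent_id": e.parent.id}
        for g in (fx.anatomy, fx.taxonomy)
        for e in g.edges
    ]
    pd.DataFrame(term_rows).to_csv(out / "terms.tsv", sep="\t", index=False)
    pd.DataFrame(edge_rows).to_csv(out / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(serialize_assertions(fx.assertions)).to_csv(
        out / "assertions.tsv", sep="\t", index=False
    )
    ann_rows = [
        {
            "entity_id": a.entity.id,
            "quality": a.quality,
            "related_entity_id": a.related_entity.id if a.related_entity else "",
            "taxon_id": a.organism_taxon.id,
            "source": a.source,
        }
        for a in fx.annotations
    ]
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    (out / "expectations.json").write_text(
        json.dumps(fx.expectations, indent=2, sort_keys=True) + "\n"
    )


def load_fixture(fixture_dir: str | Path) -> DemoFixture:
    d = Path(fixture_dir)
    terms = pd.read_csv(d / "terms.tsv", sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(d / "edges.tsv", sep="\t", dtype=str).fillna("")
    anat_ids = set(terms[terms.namespace == "anatomy"].id)
    anatomy = load_ontology(
        terms[terms.namespace == "anatomy"].to_dict("records"),
        edges[edges.child_id.isin(anat_ids)].to_dict("records"),
    )
    taxonomy = load_ontology(
        terms[terms.namespace == "taxonomy"].to_dict("records"),
        edges[~edges.child_id.isin(anat_ids)].to_dict("records"),
    )
    assertions = parse_assertions(
        pd.read_csv(d / "assertions.tsv", sep="\t", dtype=str)
        .fillna("")
        .to_dict("records"),
        anatomy,
        taxonomy,
    )
    ann = pd.read_csv(d / "annotations.tsv", sep="\t", dtype=str).fillna("")
    annotations = [
        PhenotypeAnnotation(
            entity=anatomy.term(r["entity_id"]),
            quality=r["quality"],
            related_entity=(
                anatomy.term(r["related_entity_id"])
                if r["related_entity_id"]
                else None
            ),
            organism_taxon=taxonomy.term(r["taxon_id"]),
            source=r["source"],
        )
        for r in ann.to_dict("records")
    ]
    expectations = {}
    exp_path = d / "expectations.json"
    if exp_path.exists():
        expectations = json.loads(exp_path.read_text())
    return DemoFixture(
        anatomy=anatomy,
        taxonomy=taxonomy,
        assertions=assertions,
        annotations=annotations,
        expectations=expectations,
    )


# ---------------------------------------------------------------------------
# Randomized fixtures for property tests
# ---------------------------------------------------------------------------

def build_random(
    seed: int,
    n_terms: int = 30,
    n_assertions: int = 10,
    n_annotations: int = 40,
) -> DemoFixture:
    """Seeded random fixture: DAG anatomy, tree taxonomy, random assertions
    (some negated, some taxon-scoped) and annotations.  No expectations."""
    if min(n_terms, n_assertions + 1, n_annotations) <= 0:
        raise ValueError("fixture sizes must be positive")
    rng = random.Random(seed)

    term_rows = [
        {"id": f"RND:a{i}", "label": f"anat {i}", "namespace": "anatomy"}
        for i in range(n_terms)
    ]
    edge_rows = []
    seen = set()

    def add_edge(child: str, relation: str, parent: str) -> None:
        key = (child, relation, parent)
        if key not in seen and child != parent:
            seen.add(key)
            edge_rows.append(
                {"child_id": child, "relation": relation, "parent_id": parent}
            )

    # is_a edges only from higher to lower index: acyclic by construction,
    # and every term touches at least one edge (no orphans).
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.3)
        for _ in range(n_parents):
            j = rng.randrange(i)
            add_edge(f"RND:a{i}", "is_a", f"RND:a{j}")
    for _ in range(n_terms // 3):
        i = rng.randrange(1, n_terms)
        j = rng.randrange(i)
        add_edge(
            f"RND:a{i}", rng.choice(["part_of", "develops_from"]), f"RND:a{j}"
        )
    anatomy = load_ontology(term_rows, edge_rows)

    n_taxa = max(2, n_terms // 2)
    tax_rows = [
        {"id": f"RND:t{i}", "label": f"taxon {i}", "namespace": "taxonomy"}
        for i in range(n_taxa)
    ]
    tax_edges = [
        {
            "child_id": f"RND:t{i}",
            "relation": "is_a",
            "parent_id": f"RND:t{rng.randrange(i)}",
        }
        for i in range(1, n_taxa)
    ]
    taxonomy = load_ontology(tax_rows, tax_edges)

    def random_scope() -> str:
        return f"RND:t{rng.randrange(n_taxa)}" if rng.random() < 0.6 else ""

    assertion_rows = []
    while len(assertion_rows) < n_assertions:
        e1, e2 = rng.sample(range(n_terms), 2)
        kind = rng.choice(["", "serially_"])
        neg = "not_" if rng.random() < 0.2 else ""
        assertion_rows.append(
            {
                "entity1_id": f"RND:a{e1}",
                "taxon1_id": random_scope(),
                "relationship": f"{neg}{kind}homologous_to",
                "entity2_id": f"RND:a{e2}",
                "taxon2_id": random_scope(),
                "evidence_eco_ids": rng.choice(
                    ["ECO:0000060", "ECO:0000067", "ECO:0000075", ""]
                ),
                "attribution": f"R{rng.randrange(100)}",
            }
        )
    assertions = parse_assertions(assertion_rows, anatomy, taxonomy)

    annotations = [
        PhenotypeAnnotation(
            entity=anatomy.term(f"RND:a{rng.randrange(n_terms)}"),
            quality=f"q{rng.randrange(5)}",
            organism_taxon=taxonomy.term(f"RND:t{rng.randrange(n_taxa)}"),
            source=f"s{i}",
        )
        for i in range(n_annotations)
    ]
    return DemoFixture(
        anatomy=anatomy,
        taxonomy=taxonomy,
        assertions=assertions,
        annotations=annotations,
    )
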