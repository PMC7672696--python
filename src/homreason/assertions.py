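"""Curated homology assertion tables: parsing, filtering, contradiction audit.

An assertion row relates an anatomical entity (optionally restricted to a
taxon) to a second entity/taxon pair as historically or serially homologous,
or explicitly *not* so.  Negative rows are first-class records but metadata
only: they are never compiled into axioms and never license a query match —
they merely flag results as contradicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import FormatError, ReferenceError_
from .ontograph import (
    UNRESTRICTED,
    OntologyGraph,
    TaxonScope,
    TermRef,
    subsumes,
)

HISTORICAL = "historical"
SERIAL = "serial"
KINDS = (HISTORICAL, SERIAL)

#: TSV relationship keyword -> (kind, negated)
RELATIONSHIP_KEYWORDS = {
    "homologous_to": (HISTORICAL, False),
    "not_homologous_to": (HISTORICAL, True),
    "serially_homologous_to": (SERIAL, False),
    "not_serially_homologous_to": (SERIAL, True),
}

ASSERTION_COLUMNS = (
    "entity1_id",
    "taxon1_id",
    "relationship",
    "entity2_id",
    "taxon2_id",
    "evidence_eco_ids",
    "attribution",
)

# Evidence & Conclusion Ontology codes used for homology curation.
ECO_LABELS = {
    "ECO:0000027": "structural similarity evidence",
    "ECO:0000033": "traceable author statement",
    "ECO:0000034": "non-traceable author statement",
    "ECO:0000060": "positional similarity evidence",
    "ECO:0000063": "compositional similarity evidence",
    "ECO:0000067": "developmental similarity evidence",
    "ECO:0000071": "morphological similarity evidence",
    "ECO:0000075": "gene expression similarity evidence",
}


@dataclass(frozen=True)
class EvidenceRecord:
    eco: TermRef

    def __post_init__(self) -> None:
        if not self.eco.id.startswith("ECO:"):
            raise FormatError(f"evidence id {self.eco.id} lacks the ECO: prefix")

    @property
    def eco_label(self) -> str:
        return self.eco.label

    @classmethod
    def from_id(cls, eco_id: str) -> "EvidenceRecord":
        label = ECO_LABELS.get(eco_id, eco_id)
        return cls(TermRef(eco_id, label, "evidence"))


@dataclass(frozen=True)
class HomologyAssertion:
    """One curated row: two taxon-scoped sides, a kind, polarity, provenance."""

    entity1: TermRef
    scope1: TaxonScope
    kind: str
    negated: bool
    entity2: TermRef
    scope2: TaxonScope
    evidence: tuple[EvidenceRecord, ...] = ()
    attribution: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise FormatError(f"unknown homology kind {self.kind!r}")
        if self.entity1.id == self.entity2.id and self.scope1 == self.scope2:
            raise FormatError(
                f"self-homology pair rejected: {self.entity1.id} in {self.scope1}"
            )

    @property
    def sides(self) -> tuple[tuple[TermRef, TaxonScope], tuple[TermRef, TaxonScope]]:
        return ((self.entity1, self.scope1), (self.entity2, self.scope2))

    def pair_key(self) -> tuple[str, tuple[tuple[str, str], tuple[str, str]]]:
        """Orientation-free identity of the asserted pair (kind + sorted sides)."""
        sides = sorted(
            (e.id, str(s)) for e, s in self.sides
        )
        return (self.kind, (sides[0], sides[1]))


@dataclass(frozen=True)
class RelationVocabulary:
    """Object properties used for one homology kind."""

    kind: str
    assertion_property: str
    assertion_property_label: str
    member_of_property: str
    has_member_property: str

    def __post_init__(self) -> None:
        props = {
            self.assertion_property,
            self.member_of_property,
            self.has_member_property,
        }
        if len(props) != 3:
            raise FormatError("the three vocabulary properties must be distinct")


HISTORICAL_VOCAB = RelationVocabulary(
    kind=HISTORICAL,
    assertion_property="RO:HOM0000007",
    assertion_property_label="in historical homology relationship with",
    member_of_property="homdemo:historical_homology_member_of",
    has_member_property="homdemo:has_historical_homology_member",
)

SERIAL_VOCAB = RelationVocabulary(
    kind=SERIAL,
    assertion_property="RO:HOM0000027",
    assertion_property_label="in serial homology relationship with",
    member_of_property="homdemo:serial_homology_member_of",
    has_member_property="homdemo:has_serial_homology_member",
)

VOCABULARIES = {HISTORICAL: HISTORICAL_VOCAB, SERIAL: SERIAL_VOCAB}

IN_TAXON = "RO:0002162"


def _split_multi(cell: str) -> list[str]:
    return [part.strip() for part in str(cell).split(";") if part.strip()]


def parse_assertions(
    table: Iterable[Mapping[str, str]],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
) -> list[HomologyAssertion]:
    """Parse tabular assertion records, resolving ids against the two graphs.

    A blank taxon cell yields an unrestricted scope.  Evidence and attribution
    cells may hold multiple ``;``-separated entries.
    """
    out = []
    for i, row in enumerate(table):
        missing = [c for c in ASSERTION_COLUMNS if c not in row]
        if missing:
            raise FormatError(f"assertion row {i}: missing columns {missing}")
        keyword = str(row["relationship"]).strip()
        if keyword not in RELATIONSHIP_KEYWORDS:
            raise FormatError(
                f"assertion row {i}: unknown relationship keyword {keyword!r}"
            )
        kind, negated = RELATIONSHIP_KEYWORDS[keyword]

        def resolve_entity(col: str) -> TermRef:
            tid = str(row[col]).strip()
            if tid not in g_anat:
                raise ReferenceError_(
                    f"assertion row {i}: entity {tid!r} not in anatomy graph"
                )
            return g_anat.term(tid)

        def resolve_scope(col: str) -> TaxonScope:
            cell = str(row.get(col, "") or "").strip()
            if not cell or cell.lower() in ("nan", "none"):
                return UNRESTRICTED
            if cell not in g_tax:
                raise ReferenceError_(
                    f"assertion row {i}: taxon {cell!r} not in taxonomy graph"
                )
            return TaxonScope(g_tax.term(cell))

        evidence = tuple(
            EvidenceRecord.from_id(e)
            for e in _split_multi(row.get("evidence_eco_ids", "") or "")
        )
        attribution = tuple(_split_multi(row.get("attribution", "") or ""))
        out.append(
            HomologyAssertion(
                entity1=resolve_entity("entity1_id"),
                scope1=resolve_scope("taxon1_id"),
                kind=kind,
                negated=negated,
                entity2=resolve_entity("entity2_id"),
                scope2=resolve_scope("taxon2_id"),
                evidence=evidence,
                attribution=attribution,
            )
        )
    return out


def serialize_assertions(
    assertions: Sequence[HomologyAssertion],
) -> list[dict[str, str]]:
    """Inverse of :func:`parse_assertions` (round-trips the collection)."""
    keyword_for = {v: k for k, v in RELATIONSHIP_KEYWORDS.items()}
    rows = []
    for a in assertions:
        rows.append(
            {
                "entity1_id": a.entity1.id,
                "taxon1_id": "" if a.scope1.is_unrestricted else a.scope1.taxon.id,
                "relationship": keyword_for[(a.kind, a.negated)],
                "entity2_id": a.entity2.id,
                "taxon2_id": "" if a.scope2.is_unrestricted else a.scope2.taxon.id,
                "evidence_eco_ids": ";".join(e.eco.id for e in a.evidence),
                "attribution": ";".join(a.attribution),
            }
        )
    return rows


@dataclass(frozen=True)
class Contradiction:
    """A pair asserted both homologous and not homologous, identically scoped."""

    kind: str
    pair: tuple[tuple[str, str], tuple[str, str]]  # ((entity, scope), (entity, scope))
    positives: tuple[HomologyAssertion, ...]
    negatives: tuple[HomologyAssertion, ...]

    @property
    def positive_evidence(self) -> tuple[EvidenceRecord, ...]:
        return tuple(e for a in self.positives for e in a.evidence)

    @property
    def negative_evidence(self) -> tuple[EvidenceRecord, ...]:
        return tuple(e for a in self.negatives for e in a.evidence)


@dataclass
class ContradictionReport:
    contradictions: list[Contradiction] = field(default_factory=list)
    unopposed_negatives: list[HomologyAssertion] = field(default_factory=list)

    def __iter__(self):
        return iter(self.contradictions)

    def __len__(self) -> int:
        return len(self.contradictions)

    def contradicted_keys(self) -> set:
        return {(c.kind, c.pair) for c in self.contradictions}


def find_contradictions(
    assertions: Iterable[HomologyAssertion],
) -> ContradictionReport:
    """Group assertions by (kind, unordered identically-scoped pair) and report
    every group holding both polarities.  Negatives with no positive
    counterpart are listed separately, not as contradictions."""
    groups: dict = {}
    for a in assertions:
        groups.setdefault(a.pair_key(), []).append(a)
    report = ContradictionReport()
    for (kind, pair), members in sorted(groups.items()):
        pos = tuple(m for m in members if not m.negated)
        neg = tuple(m for m in members if m.negated)
        if pos and neg:
            report.contradictions.append(
                Contradiction(kind=kind, pair=pair, positives=pos, negatives=neg)
            )
        elif neg:
            report.unopposed_negatives.extend(neg)
    return report


def filter_assertions(
    assertions: Iterable[HomologyAssertion],
    kinds: Optional[set[str]] = None,
    evidence_classes: Optional[set[str]] = None,
    include_negated: bool = False,
    evidence_graph: Optional[OntologyGraph] = None,
) -> list[HomologyAssertion]:
    """Keep assertions by kind, evidence class, and polarity.

    An assertion passes the evidence filter when *any* of its evidence records
    matches a requested ECO class — by exact id, or by is_a descent when an
    evidence ontology graph is supplied.
    """

    def evidence_matches(a: HomologyAssertion) -> bool:
        if evidence_classes is None:
            return True
        for rec in a.evidence:
            if rec.eco.id in evidence_classes:
                return True
            if evidence_graph is not None and rec.eco.id in evidence_graph:
                for wanted in evidence_classes:
                    if wanted in evidence_graph and subsumes(
                        evidence_graph,
                        evidence_graph.term(rec.eco.id),
                        evidence_graph.term(wanted),
                    ):
                        return True
        return False

    out = []
    for a in assertions:
        if a.negated and not include_negated:
            continue
        if kinds is not None and a.kind not in kinds:
            continue
        if not evidence_matches(a):
            continue
        out.append(a)
    return out
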