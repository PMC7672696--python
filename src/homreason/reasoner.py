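"""Bespoke entailment engine for homology queries under REA and AVA semantics.

Queries run over a phenotype-annotation ABox (entity–quality instances tied to
organism taxa).  The quality is inert: membership is decided purely by the
anatomical entity (via is_a subsumption) and the organism taxon (via the
taxonomy).

* Under **REA** ("all-some"), an annotation matches a query for homologs of Q
  iff some positive assertion has one side containing the annotation and the
  *other* side's class falling under Q.  The query term's own annotations are
  not returned unless another assertion licenses them.
* Under **AVA** ("all-all"), annotations are members of ancestral groups; an
  annotation matches iff it shares a group with a *witness* annotation whose
  entity falls under Q (the witness may be the annotation itself, which is
  why AVA returns the query term and its subtypes).

Serial and historical assertions never mix: a serial query consults only
serial assertions/groups, and vice versa.  Negative assertions only set the
``contradicted`` flag on matches; they never add or remove matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .errors import UnsupportedModelError
from .assertions import HomologyAssertion, find_contradictions
from .axioms import AncestralGroup, ClassExpr
from .ontograph import (
    UNRESTRICTED,
    OntologyGraph,
    TaxonScope,
    TermRef,
    in_scope,
    scope_within,
    subsumes,
)

REA = "rea"
AVA = "ava"


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """An EQ instance: anatomical entity + quality, observed in a taxon."""

    entity: TermRef
    quality: str
    organism_taxon: TermRef
    related_entity: Optional[TermRef] = None
    source: str = ""

    def key(self) -> tuple[str, str, str, str]:
        return (self.entity.id, self.organism_taxon.id, self.quality, self.source)


@dataclass(frozen=True)
class HomologyQuery:
    query_entity: TermRef
    kind: str
    model: str
    query_scope: TaxonScope = UNRESTRICTED


@dataclass(frozen=True)
class Justification:
    """Why one annotation matched: the licensing assertion or group."""

    licensed_by: Union[HomologyAssertion, str]  # assertion, or AncestralGroup id
    matched_side: ClassExpr
    witness: Optional[PhenotypeAnnotation] = None  # AVA only

    def describe(self) -> str:
        if isinstance(self.licensed_by, str):
            w = self.witness.entity.id if self.witness else "-"
            return (
                f"group={self.licensed_by};side={self.matched_side.base.id};"
                f"witness={w}"
            )
        a = self.licensed_by
        return (
            f"assertion={a.entity1.id}~{a.entity2.id}[{a.kind}];"
            f"side={self.matched_side.base.id}"
        )


@dataclass(frozen=True)
class Match:
    annotation: PhenotypeAnnotation
    justification: Justification
    contradicted: bool = False


@dataclass
class QueryResult:
    query: HomologyQuery
    matches: list[Match] = field(default_factory=list)

    @property
    def entity_classes(self) -> set[str]:
        return {m.annotation.entity.id for m in self.matches}

    @property
    def entity_labels(self) -> set[str]:
        return {m.annotation.entity.label for m in self.matches}

    def annotation_keys(self) -> set[tuple[str, str, str, str]]:
        return {m.annotation.key() for m in self.matches}

    def sorted_matches(self) -> list[Match]:
        return sorted(
            self.matches,
            key=lambda m: (
                m.annotation.entity.id,
                m.annotation.organism_taxon.id,
                m.annotation.source,
                m.justification.describe(),
            ),
        )

    def __len__(self) -> int:
        return len(self.matches)


def annotation_in_side(
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
    ann: PhenotypeAnnotation,
    side: ClassExpr,
) -> bool:
    """Is the annotation an instance of the (possibly taxon-scoped) side class?"""
    return subsumes(g_anat, ann.entity, side.base) and in_scope(
        g_tax, ann.organism_taxon, side.scope
    )


def _contradicted_keys(
    assertions: Optional[Iterable[HomologyAssertion]],
) -> set:
    if assertions is None:
        return set()
    return find_contradictions(assertions).contradicted_keys()


def rea_query(
    q: HomologyQuery,
    assertions: Sequence[HomologyAssertion],
    annotations: Sequence[PhenotypeAnnotation],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
) -> QueryResult:
    """All-some query: both orientations of every reciprocal pair are tried."""
    if q.model != REA:
        raise UnsupportedModelError(f"rea_query requires model='rea', got {q.model!r}")
    contradicted = _contradicted_keys(assertions)
    result = QueryResult(query=q)
    positive = [a for a in assertions if not a.negated and a.kind == q.kind]
    for ann in annotations:
        for a in positive:
            s1, s2 = (ClassExpr(a.entity1, a.scope1), ClassExpr(a.entity2, a.scope2))
            for s_match, s_target in ((s1, s2), (s2, s1)):
                if not subsumes(g_anat, s_target.base, q.query_entity):
                    continue
                if not scope_within(g_tax, s_target.scope, q.query_scope):
                    continue
                if not annotation_in_side(g_anat, g_tax, ann, s_match):
                    continue
                result.matches.append(
                    Match(
                        annotation=ann,
                        justification=Justification(a, s_match),
                        contradicted=a.pair_key() in contradicted,
                    )
                )
                break
            else:
                continue
            break
    result.matches = QueryResult(q, result.matches).sorted_matches()
    return result


def group_members(
    g: AncestralGroup,
    annotations: Sequence[PhenotypeAnnotation],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
) -> list[tuple[PhenotypeAnnotation, ClassExpr]]:
    """Annotations falling under either side of the group, with the side."""
    out = []
    for ann in annotations:
        for side in g.sides:
            if annotation_in_side(g_anat, g_tax, ann, side):
                out.append((ann, side))
                break
    return out


def ava_query(
    q: HomologyQuery,
    groups: Sequence[AncestralGroup],
    annotations: Sequence[PhenotypeAnnotation],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
    assertions: Optional[Sequence[HomologyAssertion]] = None,
) -> QueryResult:
    """All-all query over ancestral groups, witness-based.

    ``assertions`` is optional and used only to flag contradicted matches.
    """
    if q.model != AVA:
        raise UnsupportedModelError(f"ava_query requires model='ava', got {q.model!r}")
    contradicted = _contradicted_keys(assertions)
    result = QueryResult(query=q)
    for g in groups:
        if g.kind != q.kind:
            continue
        members = group_members(g, annotations, g_anat, g_tax)
        witnesses = [
            w
            for w, _ in members
            if subsumes(g_anat, w.entity, q.query_entity)
            and (
                q.query_scope.is_unrestricted
                or in_scope(g_tax, w.organism_taxon, q.query_scope)
            )
        ]
        if not witnesses:
            continue
        witness = min(witnesses, key=PhenotypeAnnotation.key)
        flag = g.source.pair_key() in contradicted
        for ann, side in members:
            result.matches.append(
                Match(
                    annotation=ann,
                    justification=Justification(g.individual_id, side, witness),
                    contradicted=flag,
                )
            )
    result.matches = QueryResult(q, result.matches).sorted_matches()
    return result


def run_query(
    q: HomologyQuery,
    assertions: Sequence[HomologyAssertion],
    groups: Sequence[AncestralGroup],
    annotations: Sequence[PhenotypeAnnotation],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
) -> QueryResult:
    """Dispatch to the REA or AVA engine."""
    if q.model == REA:
        return rea_query(q, assertions, annotations, g_anat, g_tax)
    if q.model == AVA:
        return ava_query(q, groups, annotations, g_anat, g_tax, assertions)
    raise UnsupportedModelError(f"unknown model {q.model!r}")


def pairwise_homologous(
    a: PhenotypeAnnotation,
    b: PhenotypeAnnotation,
    kind: str,
    model: str,
    groups: Sequence[AncestralGroup],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
) -> bool:
    """Are two annotation instances entailed homologous?  Defined for AVA only
    (REA's all-some semantics never entails instance-level homology)."""
    if model != AVA:
        raise UnsupportedModelError(
            "pairwise homology between individuals is entailed only under AVA"
        )
    for g in groups:
        if g.kind != kind:
            continue
        if any(
            annotation_in_side(g_anat, g_tax, a, side) for side in g.sides
        ) and any(annotation_in_side(g_anat, g_tax, b, side) for side in g.sides):
            return True
    return False


@dataclass
class CompetencyRow:
    cq: str
    model: str
    query_entity: str
    kind: str
    computed: set[str]
    expected: set[str]
    match: bool


@dataclass
class CompetencyReport:
    rows: list[CompetencyRow] = field(default_factory=list)
    rea_expectation_matches: int = 0
    n_questions: int = 0

    def matches(self, model: str) -> int:
        return sum(r.match for r in self.rows if r.model == model)

    @property
    def all_match(self) -> bool:
        return all(r.match for r in self.rows)


def run_competency(fixture) -> CompetencyReport:
    """Run every competency question under both models against the fixture's
    expected answer sets.

    Each question is compared as an entity-class set per model; questions
    carrying annotation-level expectations (the taxon-restricted one) are
    additionally checked per annotation.  The report also counts how many
    REA answers equal the persona's expectation column.
    """
    from .axioms import compile_assertions  # local import avoids a cycle

    _, groups = compile_assertions(fixture.assertions, AVA)
    report = CompetencyReport(n_questions=len(fixture.expectations))
    for cq in sorted(fixture.expectations):
        spec = fixture.expectations[cq]
        entity = fixture.anatomy.term(spec["query_entity"])
        for model in (REA, AVA):
            q = HomologyQuery(query_entity=entity, kind=spec["kind"], model=model)
            res = run_query(
                q,
                fixture.assertions,
                groups,
                fixture.annotations,
                fixture.anatomy,
                fixture.taxonomy,
            )
            expected = set(spec[model])
            ok = res.entity_classes == expected
            ann_key = f"{model}_annotations"
            if ann_key in spec:
                computed_ann = {
                    f"{k[0]}@{k[1]}" for k in res.annotation_keys()
                }
                ok = ok and computed_ann == set(spec[ann_key])
            report.rows.append(
                CompetencyRow(
                    cq=cq,
                    model=model,
                    query_entity=entity.id,
                    kind=spec["kind"],
                    computed=res.entity_classes,
                    expected=expected,
                    match=ok,
                )
            )
            if model == REA and res.entity_classes == set(spec["expectation"]):
                report.rea_expectation_matches += 1
    return report


def prototype_annotations(
    g_anat: OntologyGraph, g_tax: OntologyGraph
) -> list[PhenotypeAnnotation]:
    """One synthetic annotation per anatomy class, at the taxonomy root.

    Supports ABox-free exploration; with taxon-scoped assertions this is more
    permissive than instance data from restricted taxa would be.
    """
    roots = sorted(
        t for t, anc in g_tax.closure.items() if anc == frozenset({t})
    )
    root = g_tax.term(roots[0]) if roots else None
    if root is None:
        raise UnsupportedModelError("taxonomy graph has no root taxon")
    return [
        PhenotypeAnnotation(
            entity=t, quality="present", organism_taxon=root, source="prototype"
        )
        for t in sorted(g_anat.terms.values())
    ]


def homology_filter(
    entities: set[TermRef],
    mode: str,
    kind: str,
    model: str,
    assertions: Sequence[HomologyAssertion],
    groups: Sequence[AncestralGroup],
    annotations: Sequence[PhenotypeAnnotation],
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
    reference_entities: Optional[set[TermRef]] = None,
) -> set[TermRef]:
    """Expand or prune an entity set by homologs (a positive/negative filter).

    Homology queries are run for each reference entity (by default the input
    set itself).  ``expand``: input plus every entity class those queries
    match.  ``exclude``: input minus any member those queries match.  The
    input is never partially modified: errors propagate before any result is
    assembled.
    """
    if mode not in ("expand", "exclude"):
        raise ValueError(f"unknown filter mode {mode!r}")
    reference = entities if reference_entities is None else reference_entities
    matched_ids: set[str] = set()
    for e in sorted(reference):
        q = HomologyQuery(query_entity=e, kind=kind, model=model)
        res = run_query(q, assertions, groups, annotations, g_anat, g_tax)
        matched_ids |= res.entity_classes
    if mode == "expand":
        extra = {g_anat.term(i) for i in matched_ids}
        return set(entities) | extra
    return {e for e in entities if e.id not in matched_ids}
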