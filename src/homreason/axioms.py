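"""Compile homology assertions into OWL axioms (REA and AVA patterns).

Two compilation targets:

* **REA** (reciprocal existential axioms) — each side of an assertion becomes
  a subclass of an existential restriction over the homology property with
  the other side as filler ("all-some" semantics; OWL EL compatible).
* **AVA** (ancestral value axioms) — a generated OWL individual stands for
  the ancestral structure; each side becomes a subclass of a hasValue
  restriction pointing at it.  Combined with an inverse-property axiom and a
  property chain (member_of ∘ has_member ⊑ homologous_to) this yields
  "all-all" semantics.

Taxon-restricted sides render as the intersection ``A and in_taxon some X``
under both models.  Axiom text is a canonical functional-style rendering that
re-parses to the identical structured form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .errors import FormatError, NegatedAssertionError, ReferenceError_
from .assertions import (
    IN_TAXON,
    HomologyAssertion,
    RelationVocabulary,
    VOCABULARIES,
)
from .ontograph import OntologyGraph, TaxonScope, TermRef, UNRESTRICTED

SUBCLASS_OF_EXISTENTIAL = "subclass_of_existential"
SUBCLASS_OF_HASVALUE = "subclass_of_hasvalue"
INVERSE_PROPERTIES = "inverse_properties"
PROPERTY_CHAIN = "property_chain"


@dataclass(frozen=True)
class ClassExpr:
    """A bare class, or the intersection ``base and in_taxon some taxon``."""

    base: TermRef
    scope: TaxonScope = UNRESTRICTED

    def render(self) -> str:
        if self.scope.is_unrestricted:
            return self.base.id
        return (
            f"ObjectIntersectionOf({self.base.id} "
            f"ObjectSomeValuesFrom({IN_TAXON} {self.scope.taxon.id}))"
        )

    def sort_key(self) -> tuple[str, str]:
        return (self.base.id, "" if self.scope.is_unrestricted else self.scope.taxon.id)


@dataclass(frozen=True)
class Axiom:
    """One structured axiom; ``rendered`` is a pure function of the fields."""

    form: str
    subject: object  # ClassExpr or property CURIE
    property: str
    filler: object  # ClassExpr, individual id, or tuple of property CURIEs

    @property
    def rendered(self) -> str:
        if self.form == SUBCLASS_OF_EXISTENTIAL:
            return (
                f"SubClassOf({self.subject.render()} "
                f"ObjectSomeValuesFrom({self.property} {self.filler.render()}))"
            )
        if self.form == SUBCLASS_OF_HASVALUE:
            return (
                f"SubClassOf({self.subject.render()} "
                f"ObjectHasValue({self.property} {self.filler}))"
            )
        if self.form == INVERSE_PROPERTIES:
            return f"InverseObjectProperties({self.subject} {self.filler})"
        if self.form == PROPERTY_CHAIN:
            chain = " ".join(self.filler)
            return f"SubObjectPropertyOf(ObjectPropertyChain({chain}) {self.property})"
        raise FormatError(f"unknown axiom form {self.form!r}")

    def __str__(self) -> str:
        return self.rendered


@dataclass(frozen=True)
class AncestralGroup:
    """The AVA ancestral individual with its two taxon-scoped member sides."""

    individual_id: str
    kind: str
    sides: tuple[ClassExpr, ClassExpr]
    source: HomologyAssertion


def _slug(label: str) -> str:
    return re.sub(r"[^0-9a-z]+", "_", label.lower()).strip("_")


def ancestor_individual_id(kind: str, sides: Sequence[ClassExpr]) -> str:
    """Deterministic id for the ancestral individual of a side pair.

    Sides are put in canonical order (sorted by base id then taxon id) and
    slugged from their labels, e.g. ``pectoral_fin_forelimb_ancestor`` for an
    unscoped pair.  A taxon-scoped side carries its taxon in the slug, which
    keeps ids injective when the same entity pair is asserted under
    different scopes.
    """
    ordered = sorted(sides, key=ClassExpr.sort_key)

    def side_slug(s: ClassExpr) -> str:
        if s.scope.is_unrestricted:
            return _slug(s.base.label)
        return f"{_slug(s.base.label)}_{_slug(s.scope.taxon.label)}"

    stem = "_".join(side_slug(s) for s in ordered)
    suffix = "_ancestor" if kind == "historical" else "_serial_ancestor"
    return stem + suffix


def _scoped_sides(a: HomologyAssertion) -> tuple[ClassExpr, ClassExpr]:
    return (
        ClassExpr(a.entity1, a.scope1),
        ClassExpr(a.entity2, a.scope2),
    )


def _require_positive(a: HomologyAssertion) -> None:
    if a.negated:
        raise NegatedAssertionError(
            f"negated assertion {a.entity1.id} / {a.entity2.id} is metadata only "
            "and cannot be compiled into axioms"
        )


def rea_axioms(
    a: HomologyAssertion, vocab: Optional[RelationVocabulary] = None
) -> tuple[Axiom, Axiom]:
    """The reciprocal pair of existential subclass axioms for one assertion."""
    _require_positive(a)
    vocab = vocab or VOCABULARIES[a.kind]
    s1, s2 = _scoped_sides(a)
    prop = vocab.assertion_property
    return (
        Axiom(SUBCLASS_OF_EXISTENTIAL, s1, prop, s2),
        Axiom(SUBCLASS_OF_EXISTENTIAL, s2, prop, s1),
    )


def ava_axioms(
    a: HomologyAssertion, vocab: Optional[RelationVocabulary] = None
) -> tuple[tuple[Axiom, Axiom], AncestralGroup]:
    """Two hasValue membership axioms plus the generated ancestral individual."""
    _require_positive(a)
    vocab = vocab or VOCABULARIES[a.kind]
    s1, s2 = _scoped_sides(a)
    ind = ancestor_individual_id(a.kind, (s1, s2))
    group = AncestralGroup(individual_id=ind, kind=a.kind, sides=(s1, s2), source=a)
    prop = vocab.member_of_property
    return (
        (
            Axiom(SUBCLASS_OF_HASVALUE, s1, prop, ind),
            Axiom(SUBCLASS_OF_HASVALUE, s2, prop, ind),
        ),
        group,
    )


def property_axioms(vocab: RelationVocabulary) -> tuple[Axiom, Axiom]:
    """Inverse + chain axioms that give AVA its all-all entailment, per kind."""
    inverse = Axiom(
        INVERSE_PROPERTIES,
        vocab.member_of_property,
        "",
        vocab.has_member_property,
    )
    chain = Axiom(
        PROPERTY_CHAIN,
        "",
        vocab.assertion_property,
        (vocab.member_of_property, vocab.has_member_property),
    )
    return (inverse, chain)


def compile_assertions(
    assertions: Iterable[HomologyAssertion], model: str
) -> tuple[list[Axiom], list[AncestralGroup]]:
    """Compile all positive assertions under one model ("rea" or "ava").

    Negated assertions are skipped (they are metadata).  For AVA the property
    axioms are emitted once per kind in use.
    """
    model = model.lower()
    if model not in ("rea", "ava"):
        raise FormatError(f"unknown homology model {model!r}")
    axioms: list[Axiom] = []
    groups: list[AncestralGroup] = []
    kinds_used: list[str] = []
    for a in assertions:
        if a.negated:
            continue
        if a.kind not in kinds_used:
            kinds_used.append(a.kind)
        if model == "rea":
            axioms.extend(rea_axioms(a))
        else:
            pair, group = ava_axioms(a)
            axioms.extend(pair)
            groups.append(group)
    if model == "ava":
        for kind in kinds_used:
            axioms.extend(property_axioms(VOCABULARIES[kind]))
    return axioms, groups


# ---------------------------------------------------------------------------
# Canonical-text parsing (round-trip of Axiom.rendered)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text)


def _parse_sexpr(tokens: list[str], pos: int):
    tok = tokens[pos]
    if tok == "(" or tok == ")":
        raise FormatError(f"unexpected {tok!r} at token {pos}")
    if pos + 1 < len(tokens) and tokens[pos + 1] == "(":
        args = []
        pos += 2
        while tokens[pos] != ")":
            node, pos = _parse_sexpr(tokens, pos)
            args.append(node)
        return (tok, args), pos + 1
    return tok, pos + 1


def _class_expr_from_node(node, resolver: Callable[[str], TermRef]) -> ClassExpr:
    if isinstance(node, str):
        return ClassExpr(resolver(node), UNRESTRICTED)
    head, args = node
    if head != "ObjectIntersectionOf" or len(args) != 2:
        raise FormatError(f"unsupported class expression {head!r}")
    base, restriction = args
    rhead, rargs = restriction
    if rhead != "ObjectSomeValuesFrom" or rargs[0] != IN_TAXON:
        raise FormatError("intersection must carry an in_taxon restriction")
    return ClassExpr(resolver(base), TaxonScope(resolver(rargs[1])))


def parse_axiom(text: str, resolver: Callable[[str], TermRef]) -> Axiom:
    """Parse a canonical rendered axiom back into its structured form.

    ``resolver`` maps a CURIE to its :class:`TermRef` (e.g. ``graph.term``).
    """
    node, end = _parse_sexpr(_tokenize(text), 0)
    if isinstance(node, str):
        raise FormatError(f"not an axiom: {text!r}")
    head, args = node
    if head == "SubClassOf":
        subject = _class_expr_from_node(args[0], resolver)
        rhead, rargs = args[1]
        if rhead == "ObjectSomeValuesFrom":
            return Axiom(
                SUBCLASS_OF_EXISTENTIAL,
                subject,
                rargs[0],
                _class_expr_from_node(rargs[1], resolver),
            )
        if rhead == "ObjectHasValue":
            return Axiom(SUBCLASS_OF_HASVALUE, subject, rargs[0], rargs[1])
        raise FormatError(f"unsupported restriction {rhead!r}")
    if head == "InverseObjectProperties":
        return Axiom(INVERSE_PROPERTIES, args[0], "", args[1])
    if head == "SubObjectPropertyOf":
        chead, cargs = args[0]
        if chead != "ObjectPropertyChain":
            raise FormatError("expected ObjectPropertyChain")
        return Axiom(PROPERTY_CHAIN, "", args[1], tuple(cargs))
    raise FormatError(f"unsupported axiom head {head!r}")


# ---------------------------------------------------------------------------
# OWL functional-style document serialization
# ---------------------------------------------------------------------------

_DOC_PREFIX = "http://purl.org/homreason/demo/"


def _iri(curie: str) -> str:
    if curie.count(":") == 1:
        prefix, local = curie.split(":")
        if prefix in ("UBERON", "RO", "ECO", "BFO"):
            return f"<http://purl.obolibrary.org/obo/{prefix}_{local}>"
    return f"<{_DOC_PREFIX}{curie.replace(':', '_')}>"


def _curie_from_iri(iri: str, known: dict[str, str]) -> str:
    body = iri.strip("<>")
    if body.startswith("http://purl.obolibrary.org/obo/"):
        tail = body.rsplit("/", 1)[1]
        return tail.replace("_", ":", 1)
    if body.startswith(_DOC_PREFIX):
        mangled = body[len(_DOC_PREFIX):]
        return known.get(mangled, mangled.replace("_", ":", 1))
    raise FormatError(f"unrecognised IRI {iri!r}")


def _iri_encode(rendered: str) -> str:
    """Replace every CURIE token in a rendered axiom with its full IRI."""
    def repl(m: re.Match) -> str:
        tok = m.group(0)
        if tok in ("(", ")") or tok.endswith("Of") or tok.startswith("Object"):
            return tok
        if tok in (
            "SubClassOf",
            "InverseObjectProperties",
            "SubObjectPropertyOf",
        ):
            return tok
        if ":" in tok:
            return _iri(tok)
        # a bare token is a generated individual id
        return _iri("homdemo:" + tok)
    return _TOKEN.sub(repl, rendered)


def serialize_ontology(
    g_anat: OntologyGraph,
    g_tax: OntologyGraph,
    axioms: Sequence[Axiom],
    annotations: Optional[Sequence] = None,
) -> str:
    """Render graphs + compiled axioms as a deterministic functional-style
    OWL document: declarations, edge axioms, homology axioms, then phenotype
    instances, each block sorted lexicographically.

    Part-of and develops-from edges are emitted as existential restrictions
    (the anatomy-ontology convention); is_a edges as plain SubClassOf.
    """
    declared = set(g_anat.terms) | set(g_tax.terms)

    def check(curie: str) -> None:
        if ":" in curie and not curie.startswith(("RO:", "ECO:", "homdemo:")):
            if curie not in declared:
                raise ReferenceError_(f"dangling reference {curie} in axiom output")

    lines = [f"Ontology(<{_DOC_PREFIX}ontology>"]
    decls = []
    for g in (g_anat, g_tax):
        for t in sorted(g.terms.values()):
            decls.append(f"Declaration(Class({_iri(t.id)}))")
            decls.append(
                f'AnnotationAssertion(rdfs:label {_iri(t.id)} "{t.label}")'
            )
    for prop in sorted(
        {IN_TAXON}
        | {p for v in VOCABULARIES.values() for p in (
            v.assertion_property, v.member_of_property, v.has_member_property)}
    ):
        decls.append(f"Declaration(ObjectProperty({_iri(prop)}))")

    edge_axioms = []
    for g in (g_anat, g_tax):
        for e in g.edges:
            if e.relation == "is_a":
                edge_axioms.append(
                    f"SubClassOf({_iri(e.child.id)} {_iri(e.parent.id)})"
                )
            else:
                rel_iri = _iri(f"homdemo:{e.relation}")
                edge_axioms.append(
                    f"SubClassOf({_iri(e.child.id)} "
                    f"ObjectSomeValuesFrom({rel_iri} {_iri(e.parent.id)}))"
                )

    hom_axioms = []
    for ax in axioms:
        for expr in (ax.subject, ax.filler):
            if isinstance(expr, ClassExpr):
                check(expr.base.id)
                if not expr.scope.is_unrestricted:
                    check(expr.scope.taxon.id)
        hom_axioms.append(_iri_encode(ax.rendered))
        if ax.form == SUBCLASS_OF_HASVALUE:
            decls.append(
                f"Declaration(NamedIndividual({_iri('homdemo:' + ax.filler)}))"
            )

    instance_axioms = []
    if annotations:
        for n, ann in enumerate(
            sorted(annotations, key=lambda a: (a.entity.id, a.organism_taxon.id, a.quality))
        ):
            check(ann.entity.id)
            check(ann.organism_taxon.id)
            ind = _iri(f"homdemo:phenotype_{n:04d}")
            decls.append(f"Declaration(NamedIndividual({ind}))")
            instance_axioms.append(
                f"ClassAssertion(ObjectIntersectionOf({_iri(ann.entity.id)} "
                f"ObjectSomeValuesFrom({_iri(IN_TAXON)} "
                f"{_iri(ann.organism_taxon.id)})) {ind})"
            )

    for block in (decls, edge_axioms, hom_axioms, instance_axioms):
        lines.extend(sorted(set(block)))
    lines.append(")")
    return "\n".join(lines) + "\n"


def parse_functional_axioms(
    document: str, *graphs: OntologyGraph
) -> list[Axiom]:
    """Recover the compiled homology axioms from a serialized document.

    Only the four compiled axiom forms are reconstructed; declarations,
    labels, graph-edge axioms and instance assertions are skipped.  Term
    ids are resolved against the supplied graphs.
    """
    known = {
        t.replace(":", "_"): t for g in graphs for t in g.terms
    }

    def resolver(curie: str) -> TermRef:
        for g in graphs:
            if curie in g:
                return g.term(curie)
        raise ReferenceError_(f"undeclared term {curie} in document")

    hom_props = {
        p
        for v in VOCABULARIES.values()
        for p in (v.assertion_property, v.member_of_property, v.has_member_property)
    }
    out = []
    for line in document.splitlines():
        line = line.strip()
        if not line.startswith(
            ("SubClassOf(", "InverseObjectProperties(", "SubObjectPropertyOf(")
        ):
            continue
        curie_line = re.sub(
            r"<[^>]+>", lambda m: _curie_from_iri(m.group(0), known), line
        )
        if curie_line.startswith("SubClassOf(") and not any(
            p in curie_line for p in hom_props
        ):
            continue  # a plain graph-edge axiom, not a homology axiom
        ax = parse_axiom(curie_line, resolver)
        if ax.form == SUBCLASS_OF_HASVALUE:
            ax = Axiom(
                ax.form,
                ax.subject,
                ax.property,
                str(ax.filler).removeprefix("homdemo:"),
            )
        out.append(ax)
    return out
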