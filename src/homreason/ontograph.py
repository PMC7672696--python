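"""Ontology graphs: typed terms, typed edges, and is_a subsumption.

An :class:`OntologyGraph` holds named terms (CURIE ids) and directed edges of
three kinds — ``is_a``, ``part_of``, ``develops_from``.  Homology reasoning in
this package propagates *only* along subsumption (``is_a``): parthood and
development edges are carried for validation and display but never contribute
to the subsumption closure.  The closure is computed eagerly at load time and
graphs are treated as immutable afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import CycleError, FormatError, ReferenceError_

logger = logging.getLogger(__name__)

NAMESPACES = ("anatomy", "taxonomy", "evidence", "relation")
EDGE_RELATIONS = ("is_a", "part_of", "develops_from")


@dataclass(frozen=True, order=True)
class TermRef:
    """A named ontology term: CURIE id, display label, namespace."""

    id: str
    label: str = field(compare=False)
    namespace: str = field(compare=False)

    def __post_init__(self) -> None:
        prefix, sep, local = self.id.partition(":")
        if not (prefix and sep and local):
            raise FormatError(f"id {self.id!r} is not a CURIE (prefix:local)")
        if not self.label:
            raise FormatError(f"term {self.id} has an empty label")
        if self.namespace not in NAMESPACES:
            raise FormatError(
                f"term {self.id} has unknown namespace {self.namespace!r}"
            )


@dataclass(frozen=True)
class TaxonScope:
    """Taxonomic restriction on one side of an assertion: a taxon or nothing.

    ``TaxonScope.unrestricted()`` denotes the absence of an in_taxon
    restriction; it renders as the bare anatomy class.
    """

    taxon: Optional[TermRef] = None

    @classmethod
    def unrestricted(cls) -> "TaxonScope":
        return cls(None)

    @property
    def is_unrestricted(self) -> bool:
        return self.taxon is None

    def __str__(self) -> str:
        return "UNRESTRICTED" if self.taxon is None else self.taxon.id


UNRESTRICTED = TaxonScope.unrestricted()


@dataclass(frozen=True)
class Edge:
    child: TermRef
    relation: str
    parent: TermRef


@dataclass
class ValidationReport:
    """Soft findings: reported, never raised."""

    orphan_terms: list[str] = field(default_factory=list)
    duplicate_edges: list[tuple[str, str, str]] = field(default_factory=list)
    namespace_mixing: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.orphan_terms or self.duplicate_edges or self.namespace_mixing)

    def __str__(self) -> str:
        if self.is_clean:
            return "ok: no findings"
        lines = []
        for t in self.orphan_terms:
            lines.append(f"orphan term: {t}")
        for c, r, p in self.duplicate_edges:
            lines.append(f"duplicate edge: {c} {r} {p}")
        for c, r, p in self.namespace_mixing:
            lines.append(f"namespace mixing: {c} {r} {p}")
        return "\n".join(lines)


class OntologyGraph:
    """Terms plus typed edges with a precomputed reflexive is_a closure."""

    def __init__(self, terms: Iterable[TermRef], edges: Iterable[Edge]):
        self.terms: dict[str, TermRef] = {}
        for t in terms:
            if t.id in self.terms:
                raise FormatError(f"duplicate term id {t.id}")
            self.terms[t.id] = t
        self.edges: list[Edge] = list(edges)
        for e in self.edges:
            if e.relation not in EDGE_RELATIONS:
                raise FormatError(f"unknown relation {e.relation!r}")
            for endpoint in (e.child, e.parent):
                if endpoint.id not in self.terms:
                    raise ReferenceError_(
                        f"edge endpoint {endpoint.id} is not a declared term"
                    )
        self.closure: Mapping[str, frozenset[str]] = self._compute_closure()

    # -- construction ------------------------------------------------------

    def _isa_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (e.child.id, e.parent.id) for e in self.edges if e.relation == "is_a"
        )
        return g

    def _compute_closure(self) -> dict[str, frozenset[str]]:
        g = self._isa_digraph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise CycleError([u for u, _ in cycle])
        return {
            node: frozenset(nx.descendants(g, node)) | {node} for node in g.nodes
        }

    # -- queries -----------------------------------------------------------

    def term(self, term_id: str) -> TermRef:
        try:
            return self.terms[term_id]
        except KeyError:
            raise ReferenceError_(f"undeclared term {term_id}") from None

    def term_by_label(self, label: str) -> TermRef:
        hits = [t for t in self.terms.values() if t.label == label]
        if len(hits) != 1:
            raise ReferenceError_(f"label {label!r} matches {len(hits)} terms")
        return hits[0]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def subsumes(g: OntologyGraph, sub: TermRef, super_: TermRef) -> bool:
    """True iff ``super_`` is in the reflexive–transitive is_a closure of ``sub``."""
    if sub.id not in g.terms:
        raise ReferenceError_(f"undeclared term {sub.id}")
    if super_.id not in g.terms:
        raise ReferenceError_(f"undeclared term {super_.id}")
    return super_.id in g.closure[sub.id]


def in_scope(g_tax: OntologyGraph, taxon: TermRef, scope: TaxonScope) -> bool:
    """True iff ``taxon`` falls under the scope (vacuously for UNRESTRICTED)."""
    if scope.is_unrestricted:
        if taxon.id not in g_tax.terms:
            raise ReferenceError_(f"undeclared taxon {taxon.id}")
        return True
    return subsumes(g_tax, taxon, scope.taxon)


def scope_within(g_tax: OntologyGraph, inner: TaxonScope, outer: TaxonScope) -> bool:
    """Scope containment: every taxon admitted by ``inner`` is admitted by ``outer``."""
    if outer.is_unrestricted:
        return True
    if inner.is_unrestricted:
        return False
    return subsumes(g_tax, inner.taxon, outer.taxon)


def load_ontology(
    term_table: Iterable[Mapping[str, str]],
    edge_table: Iterable[Mapping[str, str]],
) -> OntologyGraph:
    """Build a validated graph from tabular records.

    ``term_table`` rows need keys ``id``, ``label``, ``namespace``;
    ``edge_table`` rows need ``child_id``, ``relation``, ``parent_id``.
    Input order is irrelevant to any query answer (closure is order-free).
    """
    terms = [
        TermRef(str(r["id"]), str(r["label"]), str(r["namespace"]))
        for r in term_table
    ]
    by_id = {t.id: t for t in terms}
    edges = []
    for i, r in enumerate(edge_table):
        rel = str(r["relation"])
        if rel not in EDGE_RELATIONS:
            raise FormatError(f"edge row {i}: unknown relation {rel!r}")
        try:
            child = by_id[str(r["child_id"])]
        except KeyError:
            raise ReferenceError_(
                f"edge row {i}: undeclared child {r['child_id']}"
            ) from None
        try:
            parent = by_id[str(r["parent_id"])]
        except KeyError:
            raise ReferenceError_(
                f"edge row {i}: undeclared parent {r['parent_id']}"
            ) from None
        edges.append(Edge(child, rel, parent))
    return OntologyGraph(terms, edges)


def validate(g: OntologyGraph) -> ValidationReport:
    """Report orphan terms, duplicated edges, and cross-namespace edges."""
    report = ValidationReport()
    touched = {e.child.id for e in g.edges} | {e.parent.id for e in g.edges}
    # A single-term graph has nothing to attach to; only flag orphans when
    # the graph has edges at all.
    if g.edges:
        report.orphan_terms = sorted(t for t in g.terms if t not in touched)
    seen: set[tuple[str, str, str]] = set()
    for e in g.edges:
        key = (e.child.id, e.relation, e.parent.id)
        if key in seen and key not in report.duplicate_edges:
            report.duplicate_edges.append(key)
        seen.add(key)
        if e.child.namespace != e.parent.namespace:
            report.namespace_mixing.append(key)
    return report


def read_obo(path: str, namespace: str = "anatomy") -> OntologyGraph:
    """Read a minimal OBO flat-file subset into an :class:`OntologyGraph`.

    Recognised content: ``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
    and ``relationship: part_of`` / ``relationship: develops_from``.  Any
    other relationship type is skipped with a logged warning.  Parsing is
    delegated to :mod:`obonet`.
    """
    net = __import__("obonet").read_obo(path, ignore_obsolete=True)
    term_rows = []
    for node, data in net.nodes(data=True):
        term_rows.append(
            {"id": node, "label": data.get("name", node), "namespace": namespace}
        )
    edge_rows = []
    for child, parent, rel in net.edges(keys=True):
        if rel not in EDGE_RELATIONS:
            logger.warning("ignoring unsupported OBO relationship %r", rel)
            continue
        edge_rows.append({"child_id": child, "relation": rel, "parent_id": parent})
    return load_ontology(term_rows, edge_rows)
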