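"""Independent brute-force oracles for the query engines.

These deliberately avoid the package's precomputed subsumption closure:
reachability is recomputed per call with a plain breadth-first search over
is_a edges, and the AVA oracle materializes relation triples by naive
forward chaining (membership facts, then the inverse rule, then the
property-chain rule) instead of group bookkeeping.
"""

from collections import deque


def bfs_reaches(graph, start_id, goal_id):
    """Reflexive is_a reachability by breadth-first search."""
    parents = {}
    for e in graph.edges:
        if e.relation == "is_a":
            parents.setdefault(e.child.id, []).append(e.parent.id)
    seen = {start_id}
    queue = deque([start_id])
    while queue:
        node = queue.popleft()
        if node == goal_id:
            return True
        for p in parents.get(node, ()):
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return False


def in_side(g_anat, g_tax, ann, side):
    if not bfs_reaches(g_anat, ann.entity.id, side.base.id):
        return False
    if side.scope.is_unrestricted:
        return True
    return bfs_reaches(g_tax, ann.organism_taxon.id, side.scope.taxon.id)


def naive_rea_match_keys(query_entity, kind, assertions, annotations,
                         g_anat, g_tax):
    """All-some matcher: iterate every (annotation, assertion, orientation)."""
    from homreason.axioms import ClassExpr

    matched = set()
    for ann in annotations:
        for a in assertions:
            if a.negated or a.kind != kind:
                continue
            s1 = ClassExpr(a.entity1, a.scope1)
            s2 = ClassExpr(a.entity2, a.scope2)
            for s_match, s_target in ((s1, s2), (s2, s1)):
                if not bfs_reaches(g_anat, s_target.base.id, query_entity.id):
                    continue
                if in_side(g_anat, g_tax, ann, s_match):
                    matched.add(ann.key())
    return matched


def materialized_ava_pairs(kind, groups, annotations, g_anat, g_tax):
    """Forward-chaining materializer for instance-level homology.

    Asserts member_of(ann, anc) for each annotation x group membership,
    applies the inverse rule to get has_member(anc, ann), then the chain
    member_of o has_member -> homologous, to fixpoint (one pass suffices:
    no rule feeds its own premises).  Returns unordered homologous pairs of
    annotation keys.
    """
    member_of = set()
    for g in groups:
        if g.kind != kind:
            continue
        for ann in annotations:
            if any(in_side(g_anat, g_tax, ann, side) for side in g.sides):
                member_of.add((ann.key(), g.individual_id))
    has_member = {(anc, ann) for ann, anc in member_of}
    homologous = set()
    for ann_a, anc_a in member_of:
        for anc_b, ann_b in has_member:
            if anc_a == anc_b:
                homologous.add(frozenset((ann_a, ann_b)))
    return homologous
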