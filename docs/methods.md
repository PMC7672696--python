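# Methods

## Problem setting

Comparative anatomy links phenotype data across species through statements
of homology between anatomical classes. Two kinds are modeled here:
historical homology (common ancestry across lineages) and serial homology
(repetition within a body plan). A curated assertion has the shape
*entity 1 in taxon 1 (is / is not) homologous to entity 2 in taxon 2*, with
evidence codes from the Evidence & Conclusion Ontology and literature
attributions. The question the package answers is operational: given such
assertions embedded in an anatomy ontology, which phenotype annotations
should a query for "homologs of Q" return?

## Propagation rules

Homology reasoning here propagates exclusively along `is_a` subsumption.
Parthood and development are deliberately inert: parts of homologs are not
in general homologous (fin radials vs. limb bones), and homologous
structures may arise from non-homologous precursors and vice versa, so
`part_of` and `develops_from` edges never extend a query answer. Serial and
historical homology use disjoint relation vocabularies
(`RO:HOM0000007` / `RO:HOM0000027` plus locally defined membership
properties), so neither leaks into the other: a serial query never returns
historical homologs of a serial homolog. There is also no transitive fusion
across assertions: A↔B and B↔C never entail A↔C under either model —
REA's existentials do not compose, and distinct ancestral individuals are
never merged.

## The entailment engine

Rather than delegating to a general OWL-DL reasoner, the engine computes
exactly the entailments the two axiom patterns license, over a
reflexive–transitive `is_a` closure precomputed at load time (graphs are
immutable after loading; the demo scale makes eager closure trivial).

An annotation (entity E, organism taxon T) *falls under* a taxon-scoped side
`A and in_taxon some X` iff E ⊑ A and T ⊑ X.

* **REA.** An annotation matches a query for homologs of Q of kind k iff
  some positive assertion of kind k, taken in either orientation
  (S_match, S_target), has the annotation under S_match, S_target's class
  under Q, and — when the query itself is taxon-scoped — S_target's scope
  within the query scope. This is the class-expression query
  `inheres_in some (homologous_to some Q)` unfolded against the reciprocal
  axioms.
* **AVA.** Annotations are members of an ancestral group when they fall
  under either side. An annotation matches iff it shares a group with a
  *witness* annotation whose entity falls under Q (the witness may be the
  annotation itself). This is the witness-based reading of the instance
  entailments produced by the hasValue + inverse + property-chain axioms:
  the engine reports entailed `homologous_to` links between ABox
  individuals, which is what the published Protégé demonstration queried.
  Whether the class-level entailment C ⊑ ∃homologous_to.Q should hold
  *without* an instance witness is subtle in OWL; the engine deliberately
  requires the witness. A `prototype` mode materializes one synthetic
  annotation per anatomy class at the taxonomy root for ABox-free
  exploration; because prototypes carry the root taxon, taxon-scoped
  assertions admit none of them — a documented divergence from instance
  data drawn from restricted taxa.

Qualities are inert throughout: matching depends only on the entity and the
organism taxon. Negative assertions are never compiled and never veto; they
only set a `contradicted` flag on matches whose licensing pair is also
asserted negative under the identical scopes. Contradiction detection
requires identical (unordered) scoped pairs; scope-overlapping conflicts are
deliberately not conflated with contradictions.

## Axiom generation and serialization

Each positive assertion compiles to exactly two class axioms (REA:
reciprocal existentials; AVA: two hasValue memberships plus one generated
individual), and AVA adds one inverse-property and one property-chain axiom
per kind in use. Ancestral-individual ids are pure functions of the kind
and the canonically ordered sides (sorted by base id, then taxon id),
slugged from labels; a taxon-scoped side includes its taxon in the slug so
that ids stay injective when one entity pair is asserted under different
scopes. The serializer emits an OWL functional-syntax document with every
block sorted, so output is byte-identical under input permutation; the
canonical axiom text re-parses to the identical structured form, which the
tests exercise as a round-trip invariant. No symmetry declaration is
emitted for the homology property itself: reciprocity is explicit in REA,
and AVA's inverse + chain already yield symmetric entailments.

## The demonstration fixture

`build_demo()` regenerates the fin/limb study inputs deterministically:
a 30-term anatomy graph (paired fins, limbs, buds, parts, and
`develops_from` links), a 26-taxon vertebrate taxonomy, the 11 curated
assertion rows (4 serial, 2 negative), 23 EQ phenotype annotations, and the
expected answer sets of the seven competency questions under each model.
Design choices where the source material is silent:

* Demo species lacking published taxonomy CURIEs get deterministic
  `VTO:demo:*` ids; anatomy terms keep their printed UBERON CURIEs where
  given and get `UBERON:demo:*` ids otherwise.
* Fossil and otherwise unplaced taxa (Acanthostega, Eoraptor, Dicynodontia
  directly under Tetrapoda; Triadobatrachus under Amphibia) are placed at
  the least-committal level that the taxon-restricted queries require —
  each only needs to be inside or outside Tetrapoda or Anura.
* Every graph gets a root term and every otherwise-leaf term (cleithrum,
  trunk vertebra, …) an `is_a` edge to it, as a real anatomy ontology
  would, so validation reports no orphans.
* The pre- and post-composed "small forelimb bud" phenotypes are kept as
  distinct annotations on the same entity, preserving the count of 23 and
  all set-level answers.
* Uberon-style homology *grouping classes* (paired limb/fin, pectoral
  appendage, …) are available as an optional overlay; a regression test
  confirms that enabling them changes no query answer.

The fixture is faithful to its source in structure and scale, not a sample
of real knowledgebase data: passing tests show that the axiom patterns have
the intended consequences on this graph, not that curation at
knowledgebase scale is correct or complete.

`build_random(seed, …)` emits fixtures of the same shape — indexed DAG
anatomy (edges only from higher to lower index, hence acyclic by
construction), tree taxonomy, randomly scoped and occasionally negated
assertions — for property tests. Defaults (30 terms, 10 assertions, 40
annotations) keep brute-force oracles exhaustive; the oracle-equivalence
battery runs 100 such fixtures in a few seconds.

## Verification strategy

Two independent brute-force oracles back the engines: an all-some matcher
that iterates every (annotation, assertion, orientation) triple using
per-call breadth-first reachability instead of the precomputed closure, and
a forward-chaining materializer that asserts membership triples, applies
the inverse rule and then the property chain to fixpoint, and reads off
entailed instance pairs. Property tests additionally pin down: REA ⊆ AVA
containment per query, kind isolation, negation inertness, invariance under
deletion of all `part_of`/`develops_from` edges, scope monotonicity
(widening any assertion scope never removes a match), pairwise symmetry and
within-group reflexivity under AVA, and determinism of every serialized
artifact.

## Known limitations

* The engine is not a general OWL-DL reasoner: it answers exactly the
  homology query forms above, plus validation; serialized `.ofn` output
  exists so an external reasoner can be used as a cross-check.
* Negative assertions flag, never veto; reasoning over them is out of
  scope by design.
* AVA class-level entailments without an ABox witness are not reported
  (see above).
* The published 46-assertion collection is distributed as a remote OWL
  artifact; this package regenerates only the curated demonstration subset
  and does not download or parse the full collection.
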