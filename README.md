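# homreason

Logical models of anatomical homology for comparative biology: an axiom
compiler and a bespoke entailment engine for **historical** homology
(similarity by common ancestry — pectoral fin and forelimb) and **serial**
homology (similarity of repeated structures within one organism — forelimb
and hindlimb), evaluated over an anatomy ontology, a taxonomy, and a set of
entity–quality (EQ) phenotype annotations.

The package is for curators and knowledgebase engineers who need to decide
*how* a homology assertion between two anatomical classes should propagate
through an ontology graph — and to see, concretely, what each choice of OWL
axiom pattern does and does not return for real phenotype queries.

## The two models

A curated assertion "A in taxon X is homologous to B in taxon Y" can be
compiled two ways (each side written as the class expression
`A and in_taxon some X`):

**REA — Reciprocal Existential Axioms** ("all-some", OWL EL compatible):

```
(A and in_taxon some X) SubClassOf homologous_to some (B and in_taxon some Y)
(B and in_taxon some Y) SubClassOf homologous_to some (A and in_taxon some X)
```

Every instance of A is homologous to *some* instance of B. A query for
homologs of Q returns annotations on a side whose partner side falls under
Q — so subclasses of an asserted homolog are returned, but the query term
itself and subclasses of the *query* side are not.

**AVA — Ancestral Value Axioms** ("all-all"): a generated OWL individual
stands for the ancestral structure both classes descend from,

```
(A and in_taxon some X) SubClassOf homology_member_of value ⟨a_b_ancestor⟩
(B and in_taxon some Y) SubClassOf homology_member_of value ⟨a_b_ancestor⟩
homology_member_of InverseOf has_homology_member
homology_member_of o has_homology_member SubPropertyOf homologous_to
```

which entails that every instance of A is homologous to *every* instance of
B (and to every other member of the group, including itself). Queries
additionally return the query term, its subclasses, and any superclass with
an asserted homology — at the cost of reasoning outside the scalable OWL EL
profile.

Homology never propagates through `part_of` or `develops_from` edges, only
through `is_a` subsumption; serial and historical assertions never mix; and
negative assertions (`not_homologous_to`) are metadata that flag results as
contradicted without ever vetoing them.

## Worked example

```sh
$ homreason build-demo --out demo/
$ homreason run-competency --fixture demo/
cq    model  query           kind        match  computed              expected
CQ1   rea    UBERON:0000151  historical  ok     UBERON:0000024,UBERON:0002102  ...
...
INFO homreason: rea matches 7/7, ava matches 7/7, rea-vs-expectation 5/7
```

The demonstration fixture regenerates a small fin/limb ontology, 11 curated
assertions (2 negative), and 23 phenotype annotations. Seven competency
questions probe what a comparative anatomist expects a homolog query to
return. Both models reproduce their published result columns (14/14 cells);
the REA model meets the biologist's expectation on 5 of the 7 questions —
its all-some semantics returns nothing for homologs of "forelimb wing" or
serial homologs of "hind flipper", because an existential filler cannot be
pinned to a particular subtype.

A single query, e.g. AVA historical homologs of the pectoral fin:

```sh
$ homreason query --model ava --kind historical --term UBERON:0000151 --fixture demo/
entity_id        entity_label       quality   taxon_id                    taxon_label ...
UBERON:0000024   forelimb wing      structure VTO:demo:Pteropus_giganteus Pteropus giganteus ...
UBERON:0002102   forelimb           length    VTO:demo:Eoraptor_lunensis  Eoraptor lunensis ...
UBERON:4200003   archipterygial fin present   VTO:demo:Glyptolepis        Glyptolepis ...
...
```

Each row carries a justification (which assertion or ancestral group
licensed it, and for AVA the witness annotation) and a `contradicted` flag
fed by the negative-assertion audit (`homreason check-contradictions`).

From Python, the same machinery is importable:

```python
from homreason import build_demo, compile_assertions, run_competency
fx = build_demo()
axioms, groups = compile_assertions(fx.assertions, "ava")   # 22 axioms, 9 groups
print(run_competency(fx).rea_expectation_matches)           # 5
```

`homreason generate-axioms --model {rea|ava}` serializes the merged
ontology + axioms as a deterministic OWL functional-syntax document suitable
for loading into Protégé alongside an external DL reasoner.

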