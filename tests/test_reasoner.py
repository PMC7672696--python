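import itertools

import pytest

from homreason import (
    HomologyQuery,
    annotation_in_side,
    build_demo,
    build_random,
    compile_assertions,
    homology_filter,
    pairwise_homologous,
    prototype_annotations,
    rea_query,
    run_competency,
    run_query,
)
from homreason.axioms import ClassExpr
from homreason.errors import UnsupportedModelError
from homreason.fixtures import ANATOMY_ROOT
from homreason.ontograph import TaxonScope, UNRESTRICTED, load_ontology

from conftest import label_set
from oracles import naive_rea_match_keys, materialized_ava_pairs


def _ann(demo, entity_label, taxon_label):
    for a in demo.annotations:
        if (a.entity.label == entity_label
                and a.organism_taxon.label == taxon_label):
            return a
    raise LookupError((entity_label, taxon_label))


def _query(demo, groups, label, kind, model, assertions=None):
    q = HomologyQuery(
        query_entity=demo.anatomy.term_by_label(label), kind=kind, model=model
    )
    return run_query(
        q,
        demo.assertions if assertions is None else assertions,
        groups,
        demo.annotations,
        demo.anatomy,
        demo.taxonomy,
    )


class TestAnnotationInSide:
    def test_anuran_prehallux_in_anura_scoped_side(self, demo):
        side = ClassExpr(
            demo.anatomy.term_by_label("prehallux"),
            TaxonScope(demo.taxonomy.term_by_label("Anura")),
        )
        frog = _ann(demo, "prehallux", "Callobatrachus sanyanensis")
        bat = _ann(demo, "prehallux", "Myotis lucifugus")
        assert annotation_in_side(demo.anatomy, demo.taxonomy, frog, side)
        assert not annotation_in_side(demo.anatomy, demo.taxonomy, bat, side)

    def test_everything_under_unrestricted_root(self, demo):
        root_side = ClassExpr(demo.anatomy.term(ANATOMY_ROOT), UNRESTRICTED)
        for ann in demo.annotations:
            assert annotation_in_side(
                demo.anatomy, demo.taxonomy, ann, root_side
            )


class TestREAQueries:
    def test_historical_homologs_of_pectoral_fin(self, demo, demo_groups):
        res = _query(demo, demo_groups, "pectoral fin", "historical", "rea")
        assert label_set(demo.anatomy, res.entity_classes) == {
            "forelimb", "forelimb wing"
        }

    def test_forelimb_wing_query_is_empty(self, demo, demo_groups):
        res = _query(demo, demo_groups, "forelimb wing", "historical", "rea")
        assert res.entity_classes == set()

    def test_serial_homologs_of_hindlimb(self, demo, demo_groups):
        res = _query(demo, demo_groups, "hindlimb", "serial", "rea")
        labels = label_set(demo.anatomy, res.entity_classes)
        assert labels == {"forelimb", "forelimb wing"}
        assert "hind flipper" not in labels and "pelvic fin" not in labels

    def test_justifications_never_cite_negated_assertions(self, demo,
                                                          demo_groups):
        for label, kind in [("pectoral fin", "historical"),
                            ("pedal digit 1", "historical"),
                            ("hindlimb", "serial")]:
            res = _query(demo, demo_groups, label, kind, "rea")
            for m in res.matches:
                assert not m.justification.licensed_by.negated

    def test_prehallux_match_is_flagged_contradicted(self, demo, demo_groups):
        res = _query(demo, demo_groups, "pedal digit 1", "historical", "rea")
        assert len(res) == 1 and res.matches[0].contradicted
        res2 = _query(demo, demo_groups, "pectoral fin", "historical", "rea")
        assert not any(m.contradicted for m in res2.matches)


class TestAVAQueries:
    def test_historical_homologs_of_forelimb_wing(self, demo, demo_groups):
        res = _query(demo, demo_groups, "forelimb wing", "historical", "ava")
        assert label_set(demo.anatomy, res.entity_classes) == {
            "forelimb", "pectoral fin", "archipterygial fin", "forelimb wing"
        }

    def test_serial_homologs_of_hind_flipper(self, demo, demo_groups):
        res = _query(demo, demo_groups, "hind flipper", "serial", "ava")
        assert label_set(demo.anatomy, res.entity_classes) == {
            "forelimb", "forelimb wing", "hindlimb", "hind flipper"
        }

    def test_every_match_has_a_witness_under_the_query_term(self, demo,
                                                            demo_groups):
        from homreason.ontograph import subsumes

        res = _query(demo, demo_groups, "hindlimb", "serial", "ava")
        query_term = demo.anatomy.term_by_label("hindlimb")
        for m in res.matches:
            w = m.justification.witness
            assert w is not None
            assert subsumes(demo.anatomy, w.entity, query_term)

    def test_general_assertion_scenario(self, scenario):
        _, groups = compile_assertions(scenario.assertions, "ava")
        ava = _query(scenario, groups, "pectoral fin", "historical", "ava")
        rea = _query(scenario, groups, "pectoral fin", "historical", "rea")
        ava_labels = label_set(scenario.anatomy, ava.entity_classes)
        assert {"hindlimb", "hind flipper", "forelimb"} <= ava_labels
        assert label_set(scenario.anatomy, rea.entity_classes) == {
            "forelimb", "forelimb wing"
        }


class TestPairwise:
    def test_fin_and_limb_instances_are_homologous(self, demo, demo_groups):
        a = _ann(demo, "forelimb", "Eoraptor lunensis")
        b = _ann(demo, "pectoral fin", "Acestrorhynchus pantaneiro")
        assert pairwise_homologous(a, b, "historical", "ava", demo_groups,
                                   demo.anatomy, demo.taxonomy)
        assert pairwise_homologous(b, a, "historical", "ava", demo_groups,
                                   demo.anatomy, demo.taxonomy)

    def test_different_groups_are_not_homologous(self, demo, demo_groups):
        a = _ann(demo, "forelimb", "Eoraptor lunensis")
        b = _ann(demo, "pelvic fin", "Adrianichthys oophorus")
        assert not pairwise_homologous(a, b, "historical", "ava", demo_groups,
                                       demo.anatomy, demo.taxonomy)

    def test_reflexive_within_groups(self, demo, demo_groups):
        a = _ann(demo, "forelimb", "Eoraptor lunensis")
        assert pairwise_homologous(a, a, "historical", "ava", demo_groups,
                                   demo.anatomy, demo.taxonomy)

    def test_rea_mode_is_unsupported(self, demo, demo_groups):
        a = _ann(demo, "forelimb", "Eoraptor lunensis")
        with pytest.raises(UnsupportedModelError):
            pairwise_homologous(a, a, "historical", "rea", demo_groups,
                                demo.anatomy, demo.taxonomy)


class TestHomologyFilter:
    def _call(self, demo, groups, entities, mode, reference=None):
        return homology_filter(
            entities, mode, "historical", "rea",
            demo.assertions, groups, demo.annotations,
            demo.anatomy, demo.taxonomy,
            reference_entities=reference,
        )

    def test_expand_pectoral_fin(self, demo, demo_groups):
        pec = demo.anatomy.term_by_label("pectoral fin")
        out = self._call(demo, demo_groups, {pec}, "expand")
        assert {t.label for t in out} == {
            "pectoral fin", "forelimb", "forelimb wing"
        }

    def test_expand_empty_is_empty(self, demo, demo_groups):
        assert self._call(demo, demo_groups, set(), "expand") == set()

    def test_exclude_against_pectoral_fin_homologs(self, demo, demo_groups):
        pec = demo.anatomy.term_by_label("pectoral fin")
        forelimb = demo.anatomy.term_by_label("forelimb")
        humerus = demo.anatomy.term_by_label("humerus")
        out = self._call(demo, demo_groups, {forelimb, humerus}, "exclude",
                         reference={pec})
        assert out == {humerus}


class TestPrototypeMode:
    def test_one_annotation_per_anatomy_class_at_root(self, demo):
        anns = prototype_annotations(demo.anatomy, demo.taxonomy)
        assert len(anns) == len(demo.anatomy)
        assert {a.organism_taxon.label for a in anns} == {"Vertebrata"}

    def test_abox_free_rea_query(self, demo, demo_groups):
        anns = prototype_annotations(demo.anatomy, demo.taxonomy)
        q = HomologyQuery(
            query_entity=demo.anatomy.term_by_label("pectoral fin"),
            kind="historical", model="rea",
        )
        res = rea_query(q, demo.assertions, anns, demo.anatomy, demo.taxonomy)
        # prototypes carry the root taxon, which falls outside the
        # Tetrapoda-scoped forelimb side: taxon-scoped assertions admit no
        # prototype, the documented divergence of this mode
        assert res.entity_classes == set()


class TestInvariants:
    CQS = [
        ("pectoral fin", "historical"),
        ("forelimb wing", "historical"),
        ("pectoral fin bud", "historical"),
        ("pedal digit 1", "historical"),
        ("hindlimb", "serial"),
        ("hindlimb bud", "serial"),
        ("hind flipper", "serial"),
    ]

    def test_rea_matches_subset_of_ava(self, demo, demo_groups):
        for label, kind in self.CQS:
            rea = _query(demo, demo_groups, label, kind, "rea")
            ava = _query(demo, demo_groups, label, kind, "ava")
            assert rea.annotation_keys() <= ava.annotation_keys()

    def test_kind_isolation(self, demo, demo_groups):
        for label, kind in self.CQS:
            same_kind = [a for a in demo.assertions if a.kind == kind]
            _, sub_groups = compile_assertions(same_kind, "ava")
            for model in ("rea", "ava"):
                only = _query(demo, sub_groups, label, kind, model,
                              assertions=same_kind)
                full = _query(demo, demo_groups, label, kind, model)
                assert only.annotation_keys() == full.annotation_keys()

    def test_negation_inertness(self, demo, demo_groups):
        positives = [a for a in demo.assertions if not a.negated]
        for label, kind in self.CQS:
            with_neg = _query(demo, demo_groups, label, kind, "rea")
            without = _query(demo, demo_groups, label, kind, "rea",
                             assertions=positives)
            assert with_neg.annotation_keys() == without.annotation_keys()
            # only the flags differ
            assert not any(m.contradicted for m in without.matches)

    def test_no_parthood_or_development_leakage(self, demo, demo_groups):
        stripped_anat = load_ontology(
            [{"id": t.id, "label": t.label, "namespace": t.namespace}
             for t in demo.anatomy.terms.values()],
            [{"child_id": e.child.id, "relation": e.relation,
              "parent_id": e.parent.id}
             for e in demo.anatomy.edges if e.relation == "is_a"],
        )
        for label, kind in self.CQS:
            for model in ("rea", "ava"):
                full = _query(demo, demo_groups, label, kind, model)
                q = HomologyQuery(
                    query_entity=demo.anatomy.term_by_label(label),
                    kind=kind, model=model,
                )
                part = run_query(q, demo.assertions, demo_groups,
                                 demo.annotations, stripped_anat,
                                 demo.taxonomy)
                assert full.annotation_keys() == part.annotation_keys()

    def test_scope_monotonicity(self, demo):
        import dataclasses

        vert = TaxonScope(demo.taxonomy.term_by_label("Vertebrata"))
        widened = [
            dataclasses.replace(a, scope1=vert, scope2=vert)
            for a in demo.assertions
        ]
        _, base_groups = compile_assertions(demo.assertions, "ava")
        _, wide_groups = compile_assertions(widened, "ava")
        for label, kind in self.CQS:
            for model in ("rea", "ava"):
                narrow = _query(demo, base_groups, label, kind, model)
                q = HomologyQuery(
                    query_entity=demo.anatomy.term_by_label(label),
                    kind=kind, model=model,
                )
                wide = run_query(q, widened, wide_groups, demo.annotations,
                                 demo.anatomy, demo.taxonomy)
                assert narrow.annotation_keys() <= wide.annotation_keys()


class TestOracleEquivalence:
    """Both engines agree with independent brute-force matchers."""

    @pytest.mark.parametrize("seed", range(12))
    def test_rea_engine_equals_naive_matcher(self, seed):
        fx = build_random(seed, n_terms=25, n_assertions=10, n_annotations=30)
        entities = [fx.anatomy.term(f"RND:a{i}") for i in range(0, 25, 5)]
        for entity in entities:
            for kind in ("historical", "serial"):
                q = HomologyQuery(query_entity=entity, kind=kind, model="rea")
                res = rea_query(q, fx.assertions, fx.annotations, fx.anatomy,
                                fx.taxonomy)
                oracle = naive_rea_match_keys(
                    entity, kind, fx.assertions, fx.annotations,
                    fx.anatomy, fx.taxonomy,
                )
                assert res.annotation_keys() == oracle

    @pytest.mark.parametrize("seed", range(12))
    def test_ava_pairwise_equals_materialized_triples(self, seed):
        fx = build_random(seed + 100, n_terms=20, n_assertions=8,
                          n_annotations=20)
        _, groups = compile_assertions(fx.assertions, "ava")
        for kind in ("historical", "serial"):
            oracle = materialized_ava_pairs(
                kind, groups, fx.annotations, fx.anatomy, fx.taxonomy
            )
            for a, b in itertools.combinations_with_replacement(
                fx.annotations, 2
            ):
                expected = frozenset((a.key(), b.key())) in oracle
                got = pairwise_homologous(a, b, kind, "ava", groups,
                                          fx.anatomy, fx.taxonomy)
                assert got == expected


class TestCompetency:
    def test_all_fourteen_cells_match(self, demo):
        report = run_competency(demo)
        assert len(report.rows) == 14
        assert report.all_match

    def test_rea_agrees_with_persona_on_five_of_seven(self, demo):
        report = run_competency(demo)
        assert report.rea_expectation_matches == 5

    def test_no_assertions_no_matches(self, demo):
        empty = build_demo()
        empty.assertions = []
        report = run_competency(empty)
        assert all(r.computed == set() for r in report.rows)
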