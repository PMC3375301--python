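"""Lexical matching, axiom loading, mapping derivation and overlap statistics."""

import numpy as np
import pytest

from camp.errors import AxiomParseError, DirectionMismatchError
from camp.mapping import (
    EQUIVALENT,
    LEFT_SUBCLASS_OF_RIGHT,
    CrossMapping,
    EquivalenceAxiom,
    categorize_overlap,
    derive_mapping,
    lexical_match,
    load_axioms,
    mapping_stats,
    merge_mappings,
    normalize_label,
)
from camp.ontology import Concept, Ontology
from conftest import ontology_from_edges
from oracles import edit_distance, random_dag_edges, reachability_closure


def labeled_ontology(namespace, labels_parents):
    return Ontology(
        namespace=namespace,
        concepts={
            cid: Concept(id=cid, label=label, parents=tuple(parents))
            for cid, (label, parents) in labels_parents.items()
        },
    )


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Melena", "melena"),
        ("Hearing loss", "hearing loss"),
        ("", ""),
        ("Absent/hypoplastic  toes!", "absent hypoplastic toes"),
        ("  Spaced   out  ", "spaced out"),
    ],
)
def test_normalize_label(raw, expected):
    assert normalize_label(raw) == expected


class TestLexicalMatch:
    def test_case_insensitive_label_match(self):
        a = labeled_ontology("HP", {"HP:1": ("Melena", ())})
        b = labeled_ontology("MP", {"MP:1": ("melena", ())})
        assert lexical_match(a, b) == {
            EquivalenceAxiom("HP:1", "MP:1", EQUIVALENT, "lexical")
        }

    def test_single_mismatching_character(self):
        a = labeled_ontology("HP", {"HP:1": ("anemia", ())})
        b = labeled_ontology("MP", {"MP:1": ("anaemia", ())})
        assert edit_distance("anemia", "anaemia") == 1  # oracle agrees it is in scope
        assert len(lexical_match(a, b)) == 1

    def test_distance_two_not_matched(self):
        a = labeled_ontology("HP", {"HP:1": ("anemia", ())})
        b = labeled_ontology("MP", {"MP:1": ("anaemias", ())})
        assert edit_distance("anemia", "anaemias") == 2
        assert lexical_match(a, b) == set()

    def test_no_shared_strings_gives_empty_set(self):
        a = labeled_ontology("HP", {"HP:1": ("optic nerve hypoplasia", ())})
        b = labeled_ontology("MP", {"MP:1": ("short tail", ())})
        assert lexical_match(a, b) == set()

    def test_synonyms_participate_unless_exact_scope_requested(self):
        a = Ontology(
            namespace="HP",
            concepts={
                "HP:1": Concept(
                    id="HP:1", label="gut bleed", synonyms=(("melena", "RELATED"),)
                )
            },
        )
        b = labeled_ontology("MP", {"MP:1": ("melena", ())})
        assert len(lexical_match(a, b)) == 1
        assert lexical_match(a, b, exact_scope_only=True) == set()

    def test_obsolete_concepts_never_match(self):
        a = Ontology(
            namespace="HP",
            concepts={"HP:1": Concept(id="HP:1", label="melena", obsolete=True)},
        )
        b = labeled_ontology("MP", {"MP:1": ("melena", ())})
        assert lexical_match(a, b) == set()

    def test_matcher_agrees_with_dp_distance_oracle_on_random_words(self):
        rng = np.random.default_rng(11)
        alphabet = list("abcd")
        words = [
            "".join(rng.choice(alphabet, size=int(rng.integers(3, 7))))
            for _ in range(40)
        ]
        a = labeled_ontology(
            "HP", {f"HP:{i}": (w, ()) for i, w in enumerate(words[:20])}
        )
        b = labeled_ontology(
            "MP", {f"MP:{i}": (w, ()) for i, w in enumerate(words[20:])}
        )
        expected = {
            (f"HP:{i}", f"MP:{j}")
            for i, wa in enumerate(words[:20])
            for j, wb in enumerate(words[20:])
            if edit_distance(wa, wb) <= 1
        }
        got = {(ax.left, ax.right) for ax in lexical_match(a, b)}
        assert got == expected


class TestLoadAxioms:
    def fixture_pair(self):
        a = ontology_from_edges("HP", {"HP:1": (), "HP:2": ("HP:1",)})
        b = ontology_from_edges("MP", {"MP:1": (), "MP:2": ("MP:1",)})
        return a, b

    def test_equivalent_and_subclass_rows(self, tmp_path):
        a, b = self.fixture_pair()
        path = tmp_path / "ax.tsv"
        path.write_text("# comment\nHP:2\tequivalent\tMP:2\nHP:2\tsubclass\tMP:1\n")
        axioms = load_axioms(str(path), a, b)
        assert axioms == {
            EquivalenceAxiom("HP:2", "MP:2", EQUIVALENT, "ontological"),
            EquivalenceAxiom("HP:2", "MP:1", LEFT_SUBCLASS_OF_RIGHT, "ontological"),
        }

    def test_unknown_curie_skipped(self, tmp_path, caplog):
        a, b = self.fixture_pair()
        path = tmp_path / "ax.tsv"
        path.write_text("HP:9\tequivalent\tMP:1\nHP:1\tequivalent\tMP:1\n")
        with caplog.at_level("WARNING", logger="camp.mapping"):
            axioms = load_axioms(str(path), a, b)
        assert len(axioms) == 1
        assert any("skipped" in record.message for record in caplog.records)

    def test_malformed_row_raises(self, tmp_path):
        a, b = self.fixture_pair()
        bad_cols = tmp_path / "bad.tsv"
        bad_cols.write_text("HP:1\tMP:1\n")
        with pytest.raises(AxiomParseError):
            load_axioms(str(bad_cols), a, b)
        bad_rel = tmp_path / "rel.tsv"
        bad_rel.write_text("HP:1\tsibling\tMP:1\n")
        with pytest.raises(AxiomParseError, match="sibling"):
            load_axioms(str(bad_rel), a, b)

    def test_empty_file_gives_empty_set(self, tmp_path):
        a, b = self.fixture_pair()
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert load_axioms(str(path), a, b) == set()


class TestDeriveMapping:
    def test_fig1_forward_mapping(self, fig1):
        hpo, mp, axioms = fig1
        mapping = derive_mapping(hpo, mp, axioms, "lexical")
        expected = {
            "hearing loss",
            "abnormal hearing physiology",
            "abnormal ear physiology",
            "hearing/vestibular/ear phenotype",
            "Mammalian Phenotype",
        }
        hearing_loss = "HP:0000005"
        progressive = "HP:0000006"
        assert {mp.concepts[t].label for t in mapping.table[hearing_loss]} == expected
        assert mapping.table[progressive] == mapping.table[hearing_loss]

    def test_fig1_reverse_mapping_for_deafness(self, fig1):
        hpo, mp, axioms = fig1
        mapping = derive_mapping(mp, hpo, axioms, "lexical")
        assert {hpo.concepts[t].label for t in mapping.table["MP:0000006"]} == {
            "Hearing loss",
            "Hearing abnormality",
            "Abnormality of the ear",
            "Phenotypic abnormality",
            "All",
        }

    def test_concept_without_axiom_reach_is_unmapped(self, fig1):
        hpo, mp, axioms = fig1
        mapping = derive_mapping(hpo, mp, axioms, "lexical")
        # "All" sits above the lexical anchor, so nothing in MP subsumes it
        assert mapping.table["HP:0000001"] == frozenset()
        assert "HP:0000001" not in mapping.mapped_concepts()

    def test_anti_monotone_along_source_hierarchy(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            source, target, axioms = _random_instance(rng)
            mapping = derive_mapping(source, target, axioms)
            for concept in source.concepts.values():
                for parent in concept.parents:
                    assert mapping.table[concept.id] >= mapping.table[parent]

    def test_matches_reachability_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            source, target, axioms = _random_instance(rng)
            mapping = derive_mapping(source, target, axioms)
            _check_against_oracle(source, target, axioms, mapping)


def _random_instance(rng, max_n=25):
    na, nb = int(rng.integers(4, max_n)), int(rng.integers(4, max_n))
    sa = ontology_from_edges(
        "HA",
        {f"HA:{i}": tuple(f"HA:{p}" for c, p in random_dag_edges(na, rng) if c == i)
         for i in range(na)},
    )
    sb = ontology_from_edges(
        "MB",
        {f"MB:{i}": tuple(f"MB:{p}" for c, p in random_dag_edges(nb, rng) if c == i)
         for i in range(nb)},
    )
    axioms = set()
    for _ in range(int(rng.integers(1, 6))):
        left = f"HA:{int(rng.integers(0, na))}"
        right = f"MB:{int(rng.integers(0, nb))}"
        kind = [EQUIVALENT, LEFT_SUBCLASS_OF_RIGHT][int(rng.integers(0, 2))]
        axioms.add(EquivalenceAxiom(left, right, kind, "ontological"))
    return sa, sb, axioms


def _check_against_oracle(source, target, axioms, mapping):
    """Brute-force reachability in the merged graph via matrix powers."""
    nodes = sorted(source.concepts) + sorted(target.concepts)
    index = {n: i for i, n in enumerate(nodes)}
    edges = []
    for ont in (source, target):
        for c in ont.concepts.values():
            edges.extend((index[c.id], index[p]) for p in c.parents)
    for ax in axioms:
        if ax.kind in (EQUIVALENT, LEFT_SUBCLASS_OF_RIGHT):
            edges.append((index[ax.left], index[ax.right]))
        if ax.kind == EQUIVALENT:
            edges.append((index[ax.right], index[ax.left]))
    target_ids = set(target.concepts)
    for c in source.concepts:
        reach = reachability_closure(len(nodes), edges, {index[c]})
        expected = {nodes[i] for i in reach} & target_ids - {c}
        assert mapping.table[c] == expected, c


class TestMergeMappings:
    def test_merged_contains_both_inputs_per_concept(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            source, target, ont_axioms = _random_instance(rng, max_n=15)
            lex_axioms = {
                EquivalenceAxiom(
                    f"HA:{int(rng.integers(0, len(source.concepts)))}",
                    f"MB:{int(rng.integers(0, len(target.concepts)))}",
                    EQUIVALENT,
                    "lexical",
                )
            }
            lex = derive_mapping(source, target, lex_axioms, "lexical")
            ont = derive_mapping(source, target, ont_axioms, "ontological")
            merged = merge_mappings(lex_axioms, ont_axioms, source, target)
            assert merged.provenance == "merged"
            for c in source.concepts:
                assert merged.table[c] >= lex.table[c]
                assert merged.table[c] >= ont.table[c]

    def test_empty_ontological_axioms_is_neutral(self, fig1):
        hpo, mp, lex_axioms = fig1
        lex = derive_mapping(hpo, mp, lex_axioms, "lexical")
        merged = merge_mappings(lex_axioms, set(), hpo, mp)
        assert merged.table == lex.table

    def test_union_reaches_strictly_more_than_union_of_tables(self):
        # Alternating path: HP:c is lexically equivalent to MP:x; MP:x's super
        # MP:y is (ontologically) equivalent to HP:e, and HP:e is a subclass of
        # MP:q. From HP:c, MP:q is reachable only over the *union* of the two
        # axiom sets — merging mapping tables instead would miss it.
        source = ontology_from_edges(
            "HP", {"HP:r": (), "HP:c": ("HP:r",), "HP:e": ("HP:r",)}
        )
        target = ontology_from_edges(
            "MP",
            {"MP:r": (), "MP:y": ("MP:r",), "MP:x": ("MP:y",), "MP:q": ("MP:r",)},
        )
        lex = {EquivalenceAxiom("HP:c", "MP:x", EQUIVALENT, "lexical")}
        ont = {
            EquivalenceAxiom("HP:e", "MP:y", EQUIVALENT, "ontological"),
            EquivalenceAxiom("HP:e", "MP:q", LEFT_SUBCLASS_OF_RIGHT, "ontological"),
        }
        lex_only = derive_mapping(source, target, lex).table["HP:c"]
        ont_only = derive_mapping(source, target, ont).table["HP:c"]
        merged = merge_mappings(lex, ont, source, target)
        assert lex_only == {"MP:x", "MP:y", "MP:r"}
        assert ont_only == frozenset()
        assert merged.table["HP:c"] == {"MP:x", "MP:y", "MP:r", "MP:q"}
        assert merged.table["HP:c"] > (lex_only | ont_only)


class TestOverlapAndStats:
    def make_mapping(self, table, provenance="lexical"):
        return CrossMapping(
            source="HP",
            target="MP",
            provenance=provenance,
            table={k: frozenset(v) for k, v in table.items()},
        )

    def test_forced_categories(self):
        lex = self.make_mapping(
            {"HP:1": {"x"}, "HP:2": {"x"}, "HP:3": {"x", "z"}, "HP:4": {"x", "y"}}
        )
        ont = self.make_mapping(
            {"HP:1": {"x"}, "HP:2": {"x", "y"}, "HP:3": {"x", "y"}, "HP:4": {"x"}},
            "ontological",
        )
        summary = categorize_overlap(lex, ont)
        assert summary.categories == {
            "HP:1": "exact",
            "HP:2": "lexical_subset_of_ontological",
            "HP:3": "partial_overlap",
            "HP:4": "ontological_subset_of_lexical",
        }
        assert sum(summary.counts.values()) == summary.n_comapped == 4

    def test_only_co_mapped_concepts_categorized(self):
        lex = self.make_mapping({"HP:1": {"x"}, "HP:2": set()})
        ont = self.make_mapping({"HP:1": {"x"}, "HP:2": {"y"}}, "ontological")
        summary = categorize_overlap(lex, ont)
        assert set(summary.categories) == {"HP:1"}

    def test_partition_property_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            source, target, ont_axioms = _random_instance(rng, max_n=15)
            lex_axioms = {
                EquivalenceAxiom(
                    f"HA:{int(rng.integers(0, len(source.concepts)))}",
                    f"MB:{int(rng.integers(0, len(target.concepts)))}",
                    EQUIVALENT,
                    "lexical",
                )
            }
            lex = derive_mapping(source, target, lex_axioms, "lexical")
            ont = derive_mapping(source, target, ont_axioms, "ontological")
            summary = categorize_overlap(lex, ont)
            assert sum(summary.counts.values()) == len(
                lex.mapped_concepts() & ont.mapped_concepts()
            )

    def test_direction_mismatch_rejected(self):
        lex = self.make_mapping({"HP:1": {"x"}})
        flipped = CrossMapping(
            source="MP", target="HP", provenance="ontological", table={}
        )
        with pytest.raises(DirectionMismatchError):
            categorize_overlap(lex, flipped)

    def test_mapping_stats_hand_arithmetic(self):
        mapping = self.make_mapping(
            {"HP:1": {"x", "y"}, "HP:2": {"x"}, "HP:3": set(), "HP:4": set()}
        )
        stats = mapping_stats(mapping)
        assert stats.mean_targets == pytest.approx(1.5)
        assert stats.unmapped_fraction == pytest.approx(0.5)
        assert stats.n_mapped == 2 and stats.n_source == 4

    def test_mapping_stats_degenerate_and_single(self):
        empty = mapping_stats(self.make_mapping({"HP:1": set()}))
        assert empty.all_unmapped and empty.mean_targets == 0.0
        assert empty.unmapped_fraction == 1.0
        single = mapping_stats(self.make_mapping({"HP:1": {"a", "b", "c"}}))
        assert single.mean_targets == 3.0 and single.unmapped_fraction == 0.0

    def test_tsv_round_trip(self, fig1, tmp_path):
        hpo, mp, axioms = fig1
        mapping = derive_mapping(hpo, mp, axioms, "lexical")
        path = tmp_path / "map.tsv"
        mapping.to_tsv(str(path))
        again = CrossMapping.from_tsv(str(path))
        assert again.table == mapping.table
        assert again.direction == mapping.direction
        assert again.provenance == mapping.provenance
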