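"""Cross-ontology concept mappings.

Two phenotype ontologies (e.g. HPO and MP) are related by equivalence and
subclass axioms between atomic concepts. Axioms come from two sources:

* **lexical** — concept labels/synonyms that match with at most one
  mismatching character (Levenshtein distance ≤ 1 after normalization) are
  assumed to denote equivalent classes;
* **ontological** — a precomputed axiom table, typically the output of
  reasoning over formal (EQ-style) concept definitions, supplied as TSV.

Given a set of axioms, the *mapping* of a source concept ``c`` is the set of
target-ontology concepts that are equivalent to, or superclasses of, ``c`` in
the combined graph formed by both is_a hierarchies plus the axioms
(equivalence = subclass in both directions). The *merged* mapping is
recomputed from the union of the two axiom sets — which can reach strictly
more than the union of the two per-concept tables.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping

import edlib
import networkx as nx

from .errors import AxiomParseError, DirectionMismatchError
from .ontology import Ontology

logger = logging.getLogger(__name__)

EQUIVALENT = "equivalent"
LEFT_SUBCLASS_OF_RIGHT = "left_subclass_of_right"
RIGHT_SUBCLASS_OF_LEFT = "right_subclass_of_left"
AXIOM_KINDS = (EQUIVALENT, LEFT_SUBCLASS_OF_RIGHT, RIGHT_SUBCLASS_OF_LEFT)

LEXICAL = "lexical"
ONTOLOGICAL = "ontological"
MERGED = "merged"

_NORMALIZE_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class EquivalenceAxiom:
    """A cross-ontology axiom: ``left`` (ontology A) vs ``right`` (ontology B)."""

    left: str
    right: str
    kind: str = EQUIVALENT
    provenance: str = LEXICAL

    def __post_init__(self) -> None:
        if self.kind not in AXIOM_KINDS:
            raise ValueError(f"unknown axiom kind: {self.kind!r}")


@dataclass
class CrossMapping:
    """Per-concept mapping from one ontology into another.

    ``table`` has one entry for every non-obsolete source concept; an empty
    target set records the concept as unmapped. Every non-empty target set is
    closed under the target ontology's is_a within the axioms' reach by
    construction (it is a reachability set in the combined graph).
    """

    source: str
    target: str
    provenance: str
    table: dict[str, frozenset[str]]

    @property
    def direction(self) -> tuple[str, str]:
        return (self.source, self.target)

    def targets(self, curie: str) -> frozenset[str]:
        return self.table.get(curie, frozenset())

    def mapped_concepts(self) -> frozenset[str]:
        return frozenset(c for c, t in self.table.items() if t)

    def to_tsv(self, path: str) -> None:
        """Write as 2-column TSV (source CURIE, comma-joined sorted targets)."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(
                f"# source={self.source} target={self.target} provenance={self.provenance}\n"
            )
            for curie in sorted(self.table):
                handle.write(f"{curie}\t{','.join(sorted(self.table[curie]))}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "CrossMapping":
        source = target = provenance = ""
        table: dict[str, frozenset[str]] = {}
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    meta = dict(
                        item.split("=", 1) for item in line[1:].split() if "=" in item
                    )
                    source = meta.get("source", source)
                    target = meta.get("target", target)
                    provenance = meta.get("provenance", provenance)
                    continue
                if not line:
                    continue
                curie, _, targets = line.partition("\t")
                table[curie] = frozenset(t for t in targets.split(",") if t)
        return cls(source=source, target=target, provenance=provenance, table=table)


@dataclass
class MappingStats:
    """Summary of a cross mapping: coverage and mapping multiplicity."""

    n_source: int
    n_mapped: int
    mean_targets: float
    unmapped_fraction: float
    all_unmapped: bool = False


@dataclass
class OverlapSummary:
    """Per-concept overlap categories between two mappings plus their counts.

    Only concepts mapped (non-empty) by *both* methods are categorized; the
    four categories partition that set, so the counts always sum to
    ``n_comapped``.
    """

    categories: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    EXACT = "exact"
    LEX_SUBSET = "lexical_subset_of_ontological"
    ONT_SUBSET = "ontological_subset_of_lexical"
    PARTIAL = "partial_overlap"

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {
                key: 0
                for key in (self.EXACT, self.LEX_SUBSET, self.ONT_SUBSET, self.PARTIAL)
            }
            for category in self.categories.values():
                self.counts[category] += 1

    @property
    def n_comapped(self) -> int:
        return len(self.categories)


def normalize_label(s: str) -> str:
    """Lowercase, replace punctuation with spaces, collapse whitespace."""
    return _NORMALIZE_RE.sub(" ", s.lower()).strip()


def _candidate_strings(ont: Ontology, exact_scope_only: bool) -> dict[str, set[str]]:
    strings: dict[str, set[str]] = defaultdict(set)
    for concept in ont.concepts.values():
        if concept.obsolete:
            continue
        texts = [concept.label]
        for text, scope in concept.synonyms:
            if exact_scope_only and scope != "EXACT":
                continue
            texts.append(text)
        for text in texts:
            norm = normalize_label(text)
            if norm:
                strings[norm].add(concept.id)
    return strings


def _within_edit_distance_one(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1:
        return False
    return edlib.align(a, b, mode="NW", k=1)["editDistance"] != -1


def lexical_match(
    ontA: Ontology, ontB: Ontology, exact_scope_only: bool = False
) -> set[EquivalenceAxiom]:
    """Match concepts across two ontologies by labels and synonyms.

    Two concepts match if any of their normalized label/synonym strings are
    within Levenshtein distance 1 of each other ("at most a single
    mismatching character": substitution, insertion or deletion). Every match
    yields an *equivalence* axiom with lexical provenance. Matches within a
    single ontology are never produced.

    By default all synonym scopes participate; ``exact_scope_only`` restricts
    matching to labels plus EXACT-scope synonyms.
    """
    strings_a = _candidate_strings(ontA, exact_scope_only)
    strings_b = _candidate_strings(ontB, exact_scope_only)
    by_length_b: dict[int, list[str]] = defaultdict(list)
    for text in strings_b:
        by_length_b[len(text)].append(text)

    axioms: set[EquivalenceAxiom] = set()
    for text_a, ids_a in strings_a.items():
        matches: set[str] = set()
        if text_a in strings_b:
            matches.add(text_a)
        for length in (len(text_a) - 1, len(text_a), len(text_a) + 1):
            for text_b in by_length_b.get(length, ()):
                if text_b not in matches and _within_edit_distance_one(text_a, text_b):
                    matches.add(text_b)
        for text_b in matches:
            for left in ids_a:
                for right in strings_b[text_b]:
                    axioms.add(
                        EquivalenceAxiom(
                            left=left, right=right, kind=EQUIVALENT, provenance=LEXICAL
                        )
                    )
    logger.debug(
        "lexical matching: %d axioms between %s and %s",
        len(axioms),
        ontA.namespace,
        ontB.namespace,
    )
    return axioms


def load_axioms(path: str, ontA: Ontology, ontB: Ontology) -> set[EquivalenceAxiom]:
    """Load a precomputed cross-ontology axiom table (ontological provenance).

    Tab-separated, three columns: left CURIE, relation (``equivalent`` or
    ``subclass``), right CURIE; ``#`` starts a comment. Rows whose CURIEs do
    not resolve in the two ontologies are skipped with a warning (the skipped
    count is logged); structurally malformed rows raise
    :class:`AxiomParseError`.
    """
    axioms: set[EquivalenceAxiom] = set()
    skipped = 0
    with open(path, encoding="utf-8") as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise AxiomParseError(
                    f"{path}:{number}: expected 3 tab-separated fields, got {len(fields)}"
                )
            left, relation, right = (f.strip() for f in fields)
            if relation not in ("equivalent", "subclass"):
                raise AxiomParseError(
                    f"{path}:{number}: unknown relation {relation!r} "
                    "(expected 'equivalent' or 'subclass')"
                )
            if left in ontA and right in ontB:
                kind = EQUIVALENT if relation == "equivalent" else LEFT_SUBCLASS_OF_RIGHT
                axioms.add(
                    EquivalenceAxiom(
                        left=ontA.resolve(left),
                        right=ontB.resolve(right),
                        kind=kind,
                        provenance=ONTOLOGICAL,
                    )
                )
            elif left in ontB and right in ontA:
                # row written in the opposite orientation; normalize
                kind = EQUIVALENT if relation == "equivalent" else RIGHT_SUBCLASS_OF_LEFT
                axioms.add(
                    EquivalenceAxiom(
                        left=ontA.resolve(right),
                        right=ontB.resolve(left),
                        kind=kind,
                        provenance=ONTOLOGICAL,
                    )
                )
            else:
                skipped += 1
                logger.warning("%s:%d: unresolvable CURIE, row skipped: %r", path, number, line)
    if skipped:
        logger.warning("%s: skipped %d rows with unresolvable CURIEs", path, skipped)
    return axioms


def _combined_graph(
    source: Ontology, target: Ontology, axioms: Iterable[EquivalenceAxiom]
) -> nx.DiGraph:
    """Both is_a hierarchies plus axioms as a single subclass-of digraph.

    Edges point from subclass to superclass; an equivalence axiom contributes
    an edge in both directions, so equivalent concepts are mutually reachable.
    """
    shared = source.non_obsolete_ids() & target.non_obsolete_ids()
    if shared:
        raise ValueError(f"ontologies share concept ids (e.g. {sorted(shared)[0]})")
    graph = nx.DiGraph()
    for ont in (source, target):
        for concept in ont.concepts.values():
            if concept.obsolete:
                continue
            graph.add_node(concept.id)
            for parent in concept.parents:
                graph.add_edge(concept.id, parent)
    for axiom in axioms:
        if axiom.kind in (EQUIVALENT, LEFT_SUBCLASS_OF_RIGHT):
            graph.add_edge(axiom.left, axiom.right)
        if axiom.kind in (EQUIVALENT, RIGHT_SUBCLASS_OF_LEFT):
            graph.add_edge(axiom.right, axiom.left)
    return graph


def derive_mapping(
    source: Ontology,
    target: Ontology,
    axioms: Iterable[EquivalenceAxiom],
    provenance: str = ONTOLOGICAL,
) -> CrossMapping:
    """Map every source concept to its equivalent-or-super concepts in ``target``.

    For each non-obsolete source concept ``c``, the mapping is the set of
    non-obsolete target concepts reachable from ``c`` in the combined
    subclass graph (both is_a hierarchies plus the axioms). Concepts with an
    empty set are recorded as unmapped. Because the mapping follows the
    source hierarchy, a concept inherits the mapping reachable through its
    ancestors: subclasses map to a superset of their parents' targets.
    """
    graph = _combined_graph(source, target, axioms)
    target_ids = target.non_obsolete_ids()
    table: dict[str, frozenset[str]] = {}
    for curie in source.non_obsolete_ids():
        if curie in graph:
            reach = nx.descendants(graph, curie)
            table[curie] = frozenset(reach & target_ids)
        else:
            table[curie] = frozenset()
    return CrossMapping(
        source=source.namespace, target=target.namespace, provenance=provenance, table=table
    )


def merge_mappings(
    lexical_axioms: Iterable[EquivalenceAxiom],
    ontological_axioms: Iterable[EquivalenceAxiom],
    source: Ontology,
    target: Ontology,
) -> CrossMapping:
    """Recompute the mapping over the union of both axiom sets.

    This is not the union of the two mapping tables: closure over the merged
    axiom graph can reach concepts neither axiom set reaches alone.
    """
    merged = set(lexical_axioms) | set(ontological_axioms)
    mapping = derive_mapping(source, target, merged, provenance=MERGED)
    return mapping


def categorize_overlap(
    lexical: CrossMapping, ontological: CrossMapping
) -> OverlapSummary:
    """Compare two mappings per concept, over concepts mapped by both.

    Each co-mapped concept falls in exactly one of four categories: the two
    target sets are identical; the lexical set is a strict subset of the
    ontological one; vice versa; or the sets partially overlap (each has
    concepts the other lacks, or they are disjoint).
    """
    if lexical.direction != ontological.direction:
        raise DirectionMismatchError(
            f"mapping directions differ: {lexical.direction} vs {ontological.direction}"
        )
    categories: dict[str, str] = {}
    for curie in sorted(lexical.mapped_concepts() & ontological.mapped_concepts()):
        lex, ont = lexical.table[curie], ontological.table[curie]
        if lex == ont:
            categories[curie] = OverlapSummary.EXACT
        elif lex < ont:
            categories[curie] = OverlapSummary.LEX_SUBSET
        elif ont < lex:
            categories[curie] = OverlapSummary.ONT_SUBSET
        else:
            categories[curie] = OverlapSummary.PARTIAL
    return OverlapSummary(categories=categories)


def mapping_stats(mapping: CrossMapping) -> MappingStats:
    """Mean targets per mapped concept and the fraction of unmapped concepts."""
    n_source = len(mapping.table)
    sizes = [len(targets) for targets in mapping.table.values() if targets]
    n_mapped = len(sizes)
    if n_mapped == 0:
        return MappingStats(
            n_source=n_source,
            n_mapped=0,
            mean_targets=0.0,
            unmapped_fraction=1.0 if n_source else 0.0,
            all_unmapped=True,
        )
    return MappingStats(
        n_source=n_source,
        n_mapped=n_mapped,
        mean_targets=sum(sizes) / n_mapped,
        unmapped_fraction=(n_source - n_mapped) / n_source,
    )
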