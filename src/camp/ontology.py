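"""Phenotype ontologies as concept DAGs with superclass closure.

An ontology here is the subsumption fragment of an OBO vocabulary: concepts
(terms) with labels, synonyms and alternate ids, connected by ``is_a`` edges.
The taxonomy closure of an annotation set — the set plus all of its
superclasses up to and including the root(s) — is the basic operation that
turns a flat annotation set into a semantic profile.

Only ``is_a`` edges define the taxonomy; other OBO relationship types are
ignored. Obsolete terms are retained so that stale ids can still be resolved
through ``alt_id``, but they never participate in closure or matching.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .errors import OboParseError, OntologyStructureError, UnknownConceptError

logger = logging.getLogger(__name__)

#: Synonym scopes defined by the OBO specification.
SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")

_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s*(?P<scope>EXACT|BROAD|NARROW|RELATED)?')


@dataclass(frozen=True)
class Concept:
    """A single ontology term.

    ``synonyms`` holds ``(text, scope)`` pairs; scope is one of
    :data:`SYNONYM_SCOPES` (defaulting to ``"RELATED"`` when the OBO line
    carries none). ``parents`` are the ``is_a`` targets; obsolete concepts
    never have parents.
    """

    id: str
    label: str
    synonyms: tuple[tuple[str, str], ...] = ()
    alt_ids: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class Ontology:
    """A concept DAG keyed by CURIE, with alt_id resolution.

    ``namespace`` is the CURIE prefix the ontology's ids share (``"HP"``,
    ``"MP"``). Roots are the non-obsolete concepts with no parents; a
    synthetic root is never inserted, so multi-root ontologies pass through
    unchanged.
    """

    namespace: str
    concepts: dict[str, Concept]
    _alt_index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for concept in self.concepts.values():
            for alt in concept.alt_ids:
                if alt in self.concepts:
                    raise OntologyStructureError(
                        f"alt_id {alt} of {concept.id} collides with a primary id"
                    )
                self._alt_index[alt] = concept.id
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph = self.is_a_graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyStructureError(f"cyclic is_a hierarchy: {path}")

    def is_a_graph(self) -> nx.DiGraph:
        """Directed graph with an edge child → parent for every is_a assertion."""
        graph = nx.DiGraph()
        for concept in self.concepts.values():
            if concept.obsolete:
                continue
            graph.add_node(concept.id)
            for parent in concept.parents:
                graph.add_edge(concept.id, parent)
        return graph

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(
            c.id for c in self.concepts.values() if not c.obsolete and not c.parents
        )

    def __contains__(self, curie: str) -> bool:
        return curie in self.concepts or curie in self._alt_index

    def __len__(self) -> int:
        return len(self.concepts)

    def __getitem__(self, curie: str) -> Concept:
        return self.concepts[self.resolve(curie)]

    def resolve(self, curie: str) -> str:
        """Return the primary id for ``curie`` (itself, or via alt_id)."""
        if curie in self.concepts:
            return curie
        if curie in self._alt_index:
            return self._alt_index[curie]
        raise UnknownConceptError(curie)

    def non_obsolete_ids(self) -> frozenset[str]:
        return frozenset(c.id for c in self.concepts.values() if not c.obsolete)


def resolve_id(ont: Ontology, curie: str) -> str:
    """Resolve ``curie`` to a primary id in ``ont`` (alt_ids are honoured)."""
    return ont.resolve(curie)


def superclass_closure(ont: Ontology, ids: Iterable[str]) -> frozenset[str]:
    """Close ``ids`` under the is_a hierarchy of ``ont``.

    Returns ``ids`` (resolved to primary form) together with every ancestor
    reachable via is_a, including the root(s). Idempotent. Raises
    :class:`UnknownConceptError` for ids that do not resolve or resolve to an
    obsolete concept (obsolete terms are excluded from the taxonomy).
    """
    frontier: list[str] = []
    for curie in ids:
        primary = ont.resolve(curie)
        if ont.concepts[primary].obsolete:
            raise UnknownConceptError(curie, f"concept {curie!r} is obsolete")
        frontier.append(primary)
    closed: set[str] = set()
    while frontier:
        current = frontier.pop()
        if current in closed:
            continue
        closed.add(current)
        frontier.extend(ont.concepts[current].parents)
    return frozenset(closed)


def _infer_namespace(ids: Iterable[str]) -> str:
    prefixes: dict[str, int] = {}
    for curie in ids:
        prefix = curie.split(":", 1)[0]
        prefixes[prefix] = prefixes.get(prefix, 0) + 1
    if not prefixes:
        return ""
    return max(prefixes, key=lambda p: (prefixes[p], p))


def _prevalidate_lines(path: str) -> None:
    # obonet reports no line numbers, so malformed stanza lines are caught here.
    with open(path, encoding="utf-8") as handle:
        in_stanza = False
        for number, raw in enumerate(handle, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(f"malformed stanza header at line {number}: {raw!r}")
                in_stanza = True
                continue
            if in_stanza and ":" not in line:
                raise OboParseError(f"malformed tag line at line {number}: {raw!r}")


def _parse_synonyms(raw_synonyms: Iterable[str]) -> tuple[tuple[str, str], ...]:
    parsed = []
    for raw in raw_synonyms:
        match = _SYNONYM_RE.match(raw.strip())
        if match is None:
            continue
        parsed.append((match.group("text"), match.group("scope") or "RELATED"))
    return tuple(parsed)


def parse_obo(path: str, namespace: str | None = None) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Reads ``[Term]`` stanzas (id, name, synonym, alt_id, is_a, is_obsolete);
    all other relationship types are ignored. Obsolete terms are loaded (for
    alt_id resolution) but stripped of parents and excluded from the taxonomy.
    """
    _prevalidate_lines(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise OboParseError(f"cannot parse OBO file {path}: {exc}") from exc

    concepts: dict[str, Concept] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        concepts[node] = Concept(
            id=node,
            label=data.get("name", ""),
            synonyms=_parse_synonyms(data.get("synonym", [])),
            alt_ids=tuple(data.get("alt_id", [])),
            parents=() if obsolete else tuple(data.get("is_a", [])),
            obsolete=obsolete,
        )
    ns = namespace if namespace is not None else _infer_namespace(concepts)
    ontology = Ontology(namespace=ns, concepts=concepts)
    logger.debug("parsed %d concepts from %s (namespace %s)", len(concepts), path, ns)
    return ontology


def write_obo(ont: Ontology, path: str) -> None:
    """Write ``ont`` as an OBO 1.2 flat file (the dialect :func:`parse_obo` reads).

    Intended for toy/synthetic ontologies; round-trips through
    :func:`parse_obo` losslessly for the fields this package models.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        handle.write(f"ontology: {ont.namespace.lower() or 'toy'}\n")
        for curie in sorted(ont.concepts):
            concept = ont.concepts[curie]
            handle.write("\n[Term]\n")
            handle.write(f"id: {concept.id}\n")
            handle.write(f"name: {concept.label}\n")
            for alt in concept.alt_ids:
                handle.write(f"alt_id: {alt}\n")
            for text, scope in concept.synonyms:
                handle.write(f'synonym: "{text}" {scope} []\n')
            for parent in concept.parents:
                handle.write(f"is_a: {parent}\n")
            if concept.obsolete:
                handle.write("is_obsolete: true\n")
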