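"""Profile translation, taxonomy-closed Jaccard similarity, and ranking.

A phenotype profile is an entity (mouse model or disease) with its annotated
concept set ``raw`` and the taxonomy closure ``closed`` of that set. The
similarity between a model ``m`` and a disease ``d`` is the Jaccard index

    sim(m, d) = |P_m ∩ P_d| / |P_m ∪ P_d|

over the *closed* sets ``P_m`` and ``P_d`` expressed in a single ontology —
profiles from the other species are first translated through a cross-ontology
mapping and re-closed in the target taxonomy. Because closed sets embed the
ontology structure, the unweighted Jaccard acts as a semantic similarity: two
profiles that share no raw annotations still score above zero whenever they
share superclasses.

Genes are ranked per disease by the maximum score over the models targeting
them; tied scores receive fractional (mean) ranks by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

from scipy.stats import rankdata

from .errors import DirectionMismatchError, MixedOntologyError
from .mapping import CrossMapping
from .ontology import Ontology, superclass_closure

logger = logging.getLogger(__name__)

_TIE_METHODS = {"fractional": "average", "dense": "dense", "ordinal": "ordinal"}


@dataclass(frozen=True)
class PhenotypeProfile:
    """An entity's annotation set and its taxonomy closure."""

    entity_id: str
    ontology: str
    raw: frozenset[str]
    closed: frozenset[str]

    @classmethod
    def from_raw(
        cls, entity_id: str, ontology: Ontology, ids: Iterable[str]
    ) -> "PhenotypeProfile":
        """Resolve ``ids`` in ``ontology`` and close them under is_a."""
        raw = frozenset(ontology.resolve(curie) for curie in ids)
        return cls(
            entity_id=entity_id,
            ontology=ontology.namespace,
            raw=raw,
            closed=superclass_closure(ontology, raw),
        )


@dataclass
class SimilarityMatrix:
    """All-pairs model×disease similarity scores.

    ``scores`` maps ``(model_id, disease_id)`` to the Jaccard score.
    ``empty_models``/``empty_diseases`` flag profiles whose closed set was
    empty (they score 0 against everything).
    """

    model_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    scores: dict[tuple[str, str], float]
    empty_models: frozenset[str] = frozenset()
    empty_diseases: frozenset[str] = frozenset()

    def score(self, model_id: str, disease_id: str) -> float:
        return self.scores[(model_id, disease_id)]

    def for_disease(self, disease_id: str) -> dict[str, float]:
        if disease_id not in self.disease_ids:
            raise KeyError(f"unknown disease: {disease_id!r}")
        return {m: self.scores[(m, disease_id)] for m in self.model_ids}

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("#model_id\tdisease_id\tscore\n")
            for model_id in self.model_ids:
                for disease_id in self.disease_ids:
                    handle.write(
                        f"{model_id}\t{disease_id}\t{self.scores[(model_id, disease_id)]:.6f}\n"
                    )


@dataclass
class RankedCandidates:
    """Per-disease candidate ranking: (candidate id, score, rank) triples.

    Scores are non-increasing; tied scores share a rank according to the tie
    policy (fractional by default); candidates with equal rank are ordered by
    id for determinism.
    """

    disease_id: str
    entries: tuple[tuple[str, float, float], ...]

    def rank_of(self, candidate_id: str) -> float:
        for candidate, _, rank in self.entries:
            if candidate == candidate_id:
                return rank
        raise KeyError(f"candidate {candidate_id!r} not ranked for {self.disease_id}")

    def top(self, n: int) -> tuple[str, ...]:
        return tuple(candidate for candidate, _, _ in self.entries[:n])

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("#rank\tcandidate\tscore\n")
            for candidate, score, rank in self.entries:
                handle.write(f"{rank:g}\t{candidate}\t{score:.6f}\n")


def translate_profile(
    profile: PhenotypeProfile, mapping: CrossMapping, target: Ontology
) -> PhenotypeProfile:
    """Re-express ``profile`` in the target ontology through ``mapping``.

    The new raw set is the union of the mapped target sets of the profile's
    raw concepts; unmapped concepts are dropped (drop count logged). The
    result is then re-closed in the target taxonomy: the mapped sets contain
    superclasses only up to the axioms' reach, while the similarity requires
    full closure.
    """
    if mapping.direction != (profile.ontology, target.namespace):
        raise DirectionMismatchError(
            f"mapping {mapping.direction} cannot translate a {profile.ontology!r} "
            f"profile into {target.namespace!r}"
        )
    new_raw: set[str] = set()
    dropped = 0
    for curie in profile.raw:
        targets = mapping.targets(curie)
        if targets:
            new_raw.update(targets)
        else:
            dropped += 1
    if dropped:
        logger.info(
            "profile %s: dropped %d/%d unmapped concepts during translation",
            profile.entity_id,
            dropped,
            len(profile.raw),
        )
    if not new_raw and profile.raw:
        logger.warning("profile %s: all concepts unmapped, empty translation", profile.entity_id)
    return PhenotypeProfile(
        entity_id=profile.entity_id,
        ontology=target.namespace,
        raw=frozenset(new_raw),
        closed=superclass_closure(target, new_raw),
    )


def jaccard_similarity(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Jaccard index |a∩b|/|a∪b| over closed concept sets; 0 if the union is empty."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def score_all(
    models: Sequence[PhenotypeProfile], diseases: Sequence[PhenotypeProfile]
) -> SimilarityMatrix:
    """Score every (model, disease) pair with the closed-set Jaccard index.

    All profiles must live in the same ontology (translate first). Profiles
    with empty closed sets score 0 everywhere and are flagged.
    """
    namespaces = {p.ontology for p in models} | {p.ontology for p in diseases}
    if len(namespaces) > 1:
        raise MixedOntologyError(
            f"profiles span multiple ontologies: {sorted(namespaces)}; translate first"
        )
    scores: dict[tuple[str, str], float] = {}
    for model in models:
        for disease in diseases:
            scores[(model.entity_id, disease.entity_id)] = jaccard_similarity(
                model.closed, disease.closed
            )
    return SimilarityMatrix(
        model_ids=tuple(m.entity_id for m in models),
        disease_ids=tuple(d.entity_id for d in diseases),
        scores=scores,
        empty_models=frozenset(m.entity_id for m in models if not m.closed),
        empty_diseases=frozenset(d.entity_id for d in diseases if not d.closed),
    )


def _ranked(scored: dict[str, float], tie_method: str) -> tuple[tuple[str, float, float], ...]:
    try:
        scipy_method = _TIE_METHODS[tie_method]
    except KeyError:
        raise ValueError(
            f"unknown tie method {tie_method!r}; expected one of {sorted(_TIE_METHODS)}"
        ) from None
    ordered = sorted(scored.items(), key=lambda item: (-item[1], item[0]))
    ranks = rankdata([-score for _, score in ordered], method=scipy_method)
    return tuple(
        (candidate, score, float(rank))
        for (candidate, score), rank in zip(ordered, ranks)
    )


def gene_scores(
    matrix: SimilarityMatrix, model_genes: Mapping[str, Iterable[str]]
) -> dict[tuple[str, str], float]:
    """Lift model-level scores to gene level: max over models targeting a gene."""
    scores: dict[tuple[str, str], float] = {}
    for model_id in matrix.model_ids:
        for gene in model_genes.get(model_id, ()):
            for disease_id in matrix.disease_ids:
                key = (gene, disease_id)
                score = matrix.scores[(model_id, disease_id)]
                if key not in scores or score > scores[key]:
                    scores[key] = score
    return scores


def rank_genes(
    disease_id: str,
    matrix: SimilarityMatrix,
    model_genes: Mapping[str, Iterable[str]],
    tie_method: str = "fractional",
) -> RankedCandidates:
    """Rank genes for one disease by their best model's similarity score."""
    if disease_id not in matrix.disease_ids:
        raise KeyError(f"unknown disease: {disease_id!r}")
    per_gene: dict[str, float] = {}
    for model_id in matrix.model_ids:
        score = matrix.scores[(model_id, disease_id)]
        for gene in model_genes.get(model_id, ()):
            if gene not in per_gene or score > per_gene[gene]:
                per_gene[gene] = score
    return RankedCandidates(disease_id=disease_id, entries=_ranked(per_gene, tie_method))


def rank_models(
    disease_id: str, matrix: SimilarityMatrix, tie_method: str = "fractional"
) -> RankedCandidates:
    """Rank mouse genotypes (models) for one disease by similarity score."""
    return RankedCandidates(
        disease_id=disease_id,
        entries=_ranked(matrix.for_disease(disease_id), tie_method),
    )
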