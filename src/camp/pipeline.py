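"""End-to-end runs: load inputs, map, translate, score, rank, evaluate.

This module is glue over the library: it wires the file readers, the mapping
builders and the similarity/evaluation steps into one reproducible run, and
is what both the CLI and the acceptance checks drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import annotations, evaluation, mapping, ontology, simrank

logger = logging.getLogger(__name__)

#: Translation directions: translate diseases into MP, or models into HPO.
HP2MP = "hp2mp"
MP2HP = "mp2hp"


@dataclass
class CorpusFiles:
    """Paths of one corpus bundle (the dialects :mod:`camp.annotations` reads)."""

    source_obo: Path
    target_obo: Path
    axioms: Path
    gene_pheno: Path
    geno_disease: Path
    orthology: Path
    hpo_annotations: Path
    morbidmap: Path

    @classmethod
    def in_dir(cls, directory: str | Path) -> "CorpusFiles":
        d = Path(directory)
        return cls(
            source_obo=d / "hp.obo",
            target_obo=d / "mp.obo",
            axioms=d / "axioms.tsv",
            gene_pheno=d / "MGI_GenePheno.rpt",
            geno_disease=d / "MGI_GenoDisease.rpt",
            orthology=d / "HMD_Human5.rpt",
            hpo_annotations=d / "phenotype_annotation.tab",
            morbidmap=d / "morbidmap.txt",
        )


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    mapping: mapping.CrossMapping
    matrix: simrank.SimilarityMatrix
    rankings: dict[str, simrank.RankedCandidates]
    gene_scores: dict[tuple[str, str], float]
    labeled: evaluation.LabeledScores
    roc: evaluation.ROCResult

    def positive_ranks(self) -> dict[tuple[str, str], float]:
        """Rank of every scored positive association, keyed by (gene, disease)."""
        ranks: dict[tuple[str, str], float] = {}
        for gene, disease, _, label in self.labeled.records:
            if label == evaluation.POSITIVE:
                ranks[(gene, disease)] = self.rankings[disease].rank_of(gene)
        return ranks

    def write(self, out_dir: str | Path) -> None:
        """Write mapping, score, ranking and evaluation outputs as text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mapping.to_tsv(str(out / "mapping.tsv"))
        self.matrix.to_tsv(str(out / "scores.tsv"))
        ranks_dir = out / "ranks"
        ranks_dir.mkdir(exist_ok=True)
        for disease_id in sorted(self.rankings):
            self.rankings[disease_id].to_tsv(str(ranks_dir / f"{disease_id}.tsv"))
        self.roc.to_tsv(str(out / "roc.tsv"))
        self.roc.summary_json(
            str(out / "evaluation.json"),
            excluded_no_ortholog=self.labeled.excluded_no_ortholog,
            n_unscored_positives=len(self.labeled.unscored_positives),
        )


def build_mapping(
    source: ontology.Ontology,
    target: ontology.Ontology,
    mode: str,
    axioms_path: str | Path | None = None,
) -> mapping.CrossMapping:
    """Build a lexical, ontological or merged mapping from source to target."""
    lexical_axioms = (
        mapping.lexical_match(source, target) if mode in ("lexical", "merged") else set()
    )
    ontological_axioms: set[mapping.EquivalenceAxiom] = set()
    if mode in ("ontological", "merged"):
        if axioms_path is None:
            raise ValueError(f"mode {mode!r} requires an axiom table")
        ontological_axioms = mapping.load_axioms(str(axioms_path), source, target)
    if mode == "lexical":
        return mapping.derive_mapping(source, target, lexical_axioms, mapping.LEXICAL)
    if mode == "ontological":
        return mapping.derive_mapping(source, target, ontological_axioms, mapping.ONTOLOGICAL)
    if mode == "merged":
        return mapping.merge_mappings(lexical_axioms, ontological_axioms, source, target)
    raise ValueError(f"unknown mapping mode {mode!r}")


def run_pipeline(
    corpus_dir: str | Path,
    mapping_mode: str = "merged",
    direction: str = HP2MP,
    assoc: str = "mgi",
    tie_method: str = "fractional",
) -> PipelineResult:
    """Translate, score, rank and evaluate one corpus bundle.

    ``direction`` selects which side is translated: ``hp2mp`` re-expresses
    disease profiles in the mouse ontology, ``mp2hp`` re-expresses mouse
    models in the human one. ``assoc`` picks the positive-label source:
    mouse-side genotype–disease annotations (``mgi``) or human MorbidMap
    associations lifted through orthology (``morbidmap``).
    """
    files = CorpusFiles.in_dir(corpus_dir)
    hpo = ontology.parse_obo(str(files.source_obo))
    mp = ontology.parse_obo(str(files.target_obo))

    models = annotations.parse_gene_pheno(str(files.gene_pheno), ontology=mp)
    diseases = annotations.parse_hpo_annotations(str(files.hpo_annotations), ontology=hpo)

    model_profiles = [
        simrank.PhenotypeProfile.from_raw(m.genotype_id, mp, m.phenotypes) for m in models
    ]
    disease_profiles = [
        simrank.PhenotypeProfile.from_raw(d.disease_id, hpo, d.phenotypes) for d in diseases
    ]

    if direction == HP2MP:
        cross = build_mapping(hpo, mp, mapping_mode, files.axioms)
        disease_profiles = [
            simrank.translate_profile(p, cross, mp) for p in disease_profiles
        ]
    elif direction == MP2HP:
        cross = build_mapping(mp, hpo, mapping_mode, files.axioms)
        model_profiles = [
            simrank.translate_profile(p, cross, hpo) for p in model_profiles
        ]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    matrix = simrank.score_all(model_profiles, disease_profiles)
    model_genes = {m.genotype_id: m.gene_ids for m in models}
    rankings = {
        d.disease_id: simrank.rank_genes(d.disease_id, matrix, model_genes, tie_method)
        for d in diseases
    }
    scores = simrank.gene_scores(matrix, model_genes)

    if assoc == "mgi":
        table = annotations.parse_geno_disease(str(files.geno_disease))
        labeled = evaluation.label_pairs(scores, table)
    elif assoc == "morbidmap":
        table = annotations.parse_morbidmap(str(files.morbidmap))
        orth = annotations.parse_orthology(str(files.orthology))
        labeled = evaluation.label_pairs(scores, table, orth)
    else:
        raise ValueError(f"unknown association source {assoc!r}")
    roc = evaluation.roc_auc(labeled)

    return PipelineResult(
        mapping=cross,
        matrix=matrix,
        rankings=rankings,
        gene_scores=scores,
        labeled=labeled,
        roc=roc,
    )
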