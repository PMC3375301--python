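"""Synthetic input generation for every file dialect the pipeline reads.

Three generators:

* :func:`make_fig1_fixture` — a deterministic pair of toy hearing-loss
  hierarchies (an HPO-like chain and an MP-like chain) whose single lexically
  matchable concept pair drives the canonical worked example of mapping by
  subsumption closure.
* :func:`make_sod_fixture` — a small synthetic Septo-Optic-Dysplasia scenario
  (disease OMIM 182230 vs. Vax1/Gdf6/Marcks/Hesx1 mouse models) exercising
  translation and ranking end to end.
* :func:`make_corpus` — seeded random corpora with planted gene–disease
  associations, written in the exact dialects the :mod:`camp.annotations`
  parsers read, plus a ground-truth record for evaluation oracles. Identical
  seeds produce byte-identical bundles.

The random corpora are built from two structurally isomorphic random DAG
ontologies. Concept labels encode their index as spelled-out digit words
("shared phenotype one two"), which keeps any two distinct labels at edit
distance ≥ 2 — so the lexical matcher finds exactly the planted shared-label
pairs and nothing else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import Disease, MouseModel
from .mapping import (
    EQUIVALENT,
    LEFT_SUBCLASS_OF_RIGHT,
    ONTOLOGICAL,
    EquivalenceAxiom,
    lexical_match,
)
from .ontology import Concept, Ontology, write_obo

_DIGIT_WORDS = {
    "0": "zero", "1": "one", "2": "two", "3": "three", "4": "four",
    "5": "five", "6": "six", "7": "seven", "8": "eight", "9": "nine",
}


def _spell_index(i: int) -> str:
    """Spell an integer as digit words; distinct integers differ by ≥ 2 edits."""
    return " ".join(_DIGIT_WORDS[d] for d in str(i))


# ---------------------------------------------------------------------------
# Figure-style worked-example fixtures
# ---------------------------------------------------------------------------

_FIG1_HPO_CHAIN = (
    "All",
    "Phenotypic abnormality",
    "Abnormality of the ear",
    "Hearing abnormality",
    "Hearing loss",
    "Progressive hearing impairment",
    "Progressive childhood hearing loss",
)
_FIG1_MP_CHAIN = (
    "Mammalian Phenotype",
    "hearing/vestibular/ear phenotype",
    "abnormal ear physiology",
    "abnormal hearing physiology",
    "hearing loss",
    "deafness",
)


def _chain_ontology(namespace: str, labels: tuple[str, ...]) -> Ontology:
    concepts = {}
    for i, label in enumerate(labels, start=1):
        curie = f"{namespace}:{i:07d}"
        parents = () if i == 1 else (f"{namespace}:{i - 1:07d}",)
        concepts[curie] = Concept(id=curie, label=label, parents=parents)
    return Ontology(namespace=namespace, concepts=concepts)


def make_fig1_fixture(
    out_dir: str | os.PathLike | None = None,
) -> tuple[Ontology, Ontology, set[EquivalenceAxiom]]:
    """Build the two toy hearing-loss chains and their lexical axioms.

    The HPO-like side is a 7-concept chain (All down to Progressive childhood
    hearing loss); the MP-like side a 6-concept chain (Mammalian Phenotype
    down to deafness). Exactly one concept pair matches lexically (Hearing
    loss / hearing loss). When ``out_dir`` is given, the two ontologies are
    written there as ``hp_fig1.obo`` and ``mp_fig1.obo``. Deterministic.
    """
    hpo = _chain_ontology("HP", _FIG1_HPO_CHAIN)
    mp = _chain_ontology("MP", _FIG1_MP_CHAIN)
    axioms = lexical_match(hpo, mp)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_obo(hpo, str(out / "hp_fig1.obo"))
        write_obo(mp, str(out / "mp_fig1.obo"))
    return hpo, mp, axioms


@dataclass
class SodFixture:
    """Synthetic Septo-Optic-Dysplasia scenario (toy stand-in for real data).

    Mini ontologies, ontological axioms, an OMIM 182230 disease profile and a
    handful of mouse models (Vax1, Gdf6, Marcks, Hesx1 plus an unrelated
    decoy) with their gene assignments.
    """

    hpo: Ontology
    mp: Ontology
    axioms: set[EquivalenceAxiom]
    disease: Disease
    models: list[MouseModel]
    gene_symbols: dict[str, str]

    @property
    def model_genes(self) -> dict[str, tuple[str, ...]]:
        return {m.genotype_id: m.gene_ids for m in self.models}


def make_sod_fixture() -> SodFixture:
    """Build the synthetic SOD worked-example fixture. Deterministic."""
    hp_terms = {
        "HP:0000001": ("All", ()),
        "HP:0000118": ("Phenotypic abnormality", ("HP:0000001",)),
        "HP:0000478": ("Abnormality of the eye", ("HP:0000118",)),
        "HP:0012443": ("Abnormality of brain morphology", ("HP:0000118",)),
        "HP:0000639": ("Optic nerve hypoplasia", ("HP:0000478",)),
        "HP:0001274": ("Agenesis of corpus callosum", ("HP:0012443",)),
        "HP:0001331": ("Absent septum pellucidum", ("HP:0012443",)),
        "HP:0012506": ("Pituitary hypoplasia", ("HP:0012443",)),
    }
    mp_terms = {
        "MP:0000001": ("mammalian phenotype", ()),
        "MP:0005391": ("vision/eye phenotype", ("MP:0000001",)),
        "MP:0003631": ("nervous system phenotype", ("MP:0000001",)),
        "MP:0005390": ("skeleton phenotype", ("MP:0000001",)),
        "MP:0005371": ("limbs/digits/tail phenotype", ("MP:0000001",)),
        "MP:0001286": ("abnormal eye development", ("MP:0005391",)),
        "MP:0001330": ("abnormal optic nerve morphology", ("MP:0001286",)),
        "MP:0001325": ("abnormal retina morphology", ("MP:0001286",)),
        "MP:0002152": ("abnormal brain morphology", ("MP:0003631",)),
        "MP:0002196": ("absent corpus callosum", ("MP:0002152",)),
        "MP:0008227": ("small pituitary gland", ("MP:0002152",)),
        "MP:0005508": ("abnormal skull morphology", ("MP:0005390",)),
        "MP:0000592": ("short tail", ("MP:0005371",)),
    }
    hpo = Ontology(
        namespace="HP",
        concepts={
            cid: Concept(id=cid, label=label, parents=parents)
            for cid, (label, parents) in hp_terms.items()
        },
    )
    mp = Ontology(
        namespace="MP",
        concepts={
            cid: Concept(id=cid, label=label, parents=parents)
            for cid, (label, parents) in mp_terms.items()
        },
    )
    axioms = {
        EquivalenceAxiom("HP:0000639", "MP:0001330", LEFT_SUBCLASS_OF_RIGHT, ONTOLOGICAL),
        EquivalenceAxiom("HP:0001274", "MP:0002196", EQUIVALENT, ONTOLOGICAL),
        EquivalenceAxiom("HP:0001331", "MP:0002152", LEFT_SUBCLASS_OF_RIGHT, ONTOLOGICAL),
        EquivalenceAxiom("HP:0012506", "MP:0008227", EQUIVALENT, ONTOLOGICAL),
    }
    disease = Disease(
        disease_id="182230",
        phenotypes=frozenset(
            {"HP:0000639", "HP:0001274", "HP:0001331", "HP:0012506"}
        ),
    )
    models = [
        MouseModel(
            genotype_id="MGI:1859863",
            allele_symbols=("Vax1<tm1Grl>",),
            gene_ids=("MGI:1277163",),
            phenotypes=frozenset({"MP:0001286", "MP:0001330", "MP:0002196"}),
        ),
        MouseModel(
            genotype_id="MGI:3850001",
            allele_symbols=("Gdf6<tm1Syn>",),
            gene_ids=("MGI:95689",),
            phenotypes=frozenset({"MP:0001286", "MP:0001325", "MP:0005508"}),
        ),
        MouseModel(
            genotype_id="MGI:3850002",
            allele_symbols=("Marcks<tm1Syn>",),
            gene_ids=("MGI:96907",),
            phenotypes=frozenset({"MP:0002196", "MP:0002152", "MP:0001325"}),
        ),
        MouseModel(
            genotype_id="MGI:3850003",
            allele_symbols=("Hesx1<tm1Syn>",),
            gene_ids=("MGI:96071",),
            phenotypes=frozenset({"MP:0008227"}),
        ),
        MouseModel(
            genotype_id="MGI:3850004",
            allele_symbols=("Decoy<tm1Syn>",),
            gene_ids=("MGI:9999999",),
            phenotypes=frozenset({"MP:0000592"}),
        ),
    ]
    gene_symbols = {
        "MGI:1277163": "Vax1",
        "MGI:95689": "Gdf6",
        "MGI:96907": "Marcks",
        "MGI:96071": "Hesx1",
        "MGI:9999999": "Decoy",
    }
    return SodFixture(
        hpo=hpo, mp=mp, axioms=axioms, disease=disease, models=models,
        gene_symbols=gene_symbols,
    )


# ---------------------------------------------------------------------------
# Random corpora with planted structure
# ---------------------------------------------------------------------------


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus.

    ``p_shared`` is the probability that a disease phenotype is mirrored (via
    a planted cross-ontology pairing) in its true gene's model; ``p_noise``
    the per-term probability of a spurious extra annotation;
    ``frac_axiom_coverage`` the fraction of paired leaf concepts given an
    ontological equivalence axiom; ``frac_lexical`` the fraction of paired
    leaves whose labels are lexically identical across the two ontologies
    (the synthetic analogue of shared clinical vocabulary). Disease profiles
    draw 3–15 terms and decoy models 2–8, mimicking real annotation depth.
    """

    n_source_concepts: int = 120
    n_target_concepts: int = 120
    dag_depth: int = 4
    n_models: int = 50
    n_diseases: int = 30
    n_genes: int = 50
    p_shared: float = 0.9
    p_noise: float = 0.1
    frac_axiom_coverage: float = 0.9
    frac_lexical: float = 0.3
    seed: int = 42

    def validate(self) -> None:
        for name in ("p_shared", "p_noise", "frac_axiom_coverage", "frac_lexical"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < 1 or self.n_models < 1 or self.n_diseases < 1:
            raise ValueError("n_genes, n_models and n_diseases must be positive")
        if self.n_models < min(self.n_genes, self.n_diseases):
            raise ValueError(
                "infeasible spec: every planted gene–disease pair needs a model, "
                f"but n_models={self.n_models} < {min(self.n_genes, self.n_diseases)}"
            )
        if self.n_source_concepts < self.dag_depth + 1:
            raise ValueError("too few concepts for the requested DAG depth")


@dataclass
class CorpusTruth:
    """Ground truth for a generated corpus: planted structure plus file paths."""

    spec: CorpusSpec
    source_ontology: Ontology
    target_ontology: Ontology
    axioms: set[EquivalenceAxiom]
    mirror: dict[str, str]  # source leaf -> paired target leaf
    models: list[MouseModel]
    diseases: list[Disease]
    planted_gene: dict[str, str]  # disease id -> its true MGI gene
    orthology_pairs: list[tuple[str, str, str]]  # (mouse symbol, MGI id, human symbol)
    positives_mouse: frozenset[tuple[str, str]]
    positives_human: frozenset[tuple[str, str]]
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def model_genes(self) -> dict[str, tuple[str, ...]]:
        return {m.genotype_id: m.gene_ids for m in self.models}


def _dag_level_sizes(n: int, depth: int) -> list[int]:
    """Split n-1 non-root concepts over ``depth`` levels, widening downward."""
    weights = np.array([2.0**i for i in range(1, depth + 1)])
    sizes = np.maximum(1, np.floor((n - 1) * weights / weights.sum())).astype(int)
    while sizes.sum() > n - 1:
        sizes[int(np.argmax(sizes))] -= 1
    sizes[-1] += (n - 1) - sizes.sum()
    return [1] + sizes.tolist()


def _random_dag_topology(
    n: int, depth: int, rng: np.random.Generator
) -> list[list[int]]:
    """Parent lists per node index; node 0 is the root. Acyclic by construction."""
    sizes = _dag_level_sizes(n, depth)
    levels: list[list[int]] = []
    start = 0
    for size in sizes:
        levels.append(list(range(start, start + size)))
        start += size
    parents: list[list[int]] = [[] for _ in range(n)]
    for level_index in range(1, len(levels)):
        above = levels[level_index - 1]
        for node in levels[level_index]:
            k = int(rng.integers(1, 3)) if len(above) > 1 else 1
            chosen = rng.choice(len(above), size=min(k, len(above)), replace=False)
            parents[node] = sorted(above[i] for i in np.atleast_1d(chosen))
    return parents


def _materialize_pair(
    spec: CorpusSpec, rng: np.random.Generator
) -> tuple[Ontology, Ontology, list[str], list[str], set[int]]:
    """Build the two isomorphic ontologies; returns leaf id lists and shared-label set."""
    n = min(spec.n_source_concepts, spec.n_target_concepts)
    topology = _random_dag_topology(n, spec.dag_depth, rng)
    has_child = {p for plist in topology for p in plist}
    leaves = [i for i in range(n) if i not in has_child]
    shared = {
        int(i)
        for i in rng.choice(
            leaves, size=int(round(spec.frac_lexical * len(leaves))), replace=False
        )
    }

    def build(namespace: str, species_word: str) -> Ontology:
        concepts = {}
        for i in range(n):
            curie = f"{namespace}:{i + 1:07d}"
            if i in shared:
                label = f"shared phenotype {_spell_index(i)}"
            else:
                label = f"{species_word} phenotype {_spell_index(i)}"
            concepts[curie] = Concept(
                id=curie,
                label=label,
                parents=tuple(f"{namespace}:{p + 1:07d}" for p in topology[i]),
            )
        return Ontology(namespace=namespace, concepts=concepts)

    source = build("HPX", "human")
    target = build("MPX", "mouse")
    source_leaves = [f"HPX:{i + 1:07d}" for i in leaves]
    target_leaves = [f"MPX:{i + 1:07d}" for i in leaves]
    return source, target, source_leaves, target_leaves, shared


def make_corpus(spec: CorpusSpec, out_dir: str | os.PathLike) -> CorpusTruth:
    """Generate a full synthetic corpus under ``out_dir``.

    Writes ``hp.obo``, ``mp.obo``, ``axioms.tsv``, ``MGI_GenePheno.rpt``,
    ``MGI_GenoDisease.rpt``, ``HMD_Human5.rpt``, ``phenotype_annotation.tab``
    and ``morbidmap.txt``, all in the dialects read by
    :mod:`camp.annotations`. Identical specs (including the seed) produce
    byte-identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    source, target, source_leaves, target_leaves, _ = _materialize_pair(spec, rng)
    mirror = dict(zip(source_leaves, target_leaves))

    n_leaves = len(source_leaves)
    axiom_count = int(round(spec.frac_axiom_coverage * n_leaves))
    axiom_indices = sorted(
        int(i) for i in rng.choice(n_leaves, size=axiom_count, replace=False)
    )
    axioms = {
        EquivalenceAxiom(
            source_leaves[i], target_leaves[i], EQUIVALENT, ONTOLOGICAL
        )
        for i in axiom_indices
    }

    # genes, models, diseases with planted associations
    gene_ids = [f"MGI:{2000000 + i}" for i in range(spec.n_genes)]
    human_symbols = [f"GENE{i}" for i in range(spec.n_genes)]
    mouse_symbols = [f"Gene{i}" for i in range(spec.n_genes)]

    diseases: list[Disease] = []
    disease_terms: dict[str, list[str]] = {}
    for k in range(spec.n_diseases):
        size = int(rng.integers(3, 16))
        terms = sorted(
            source_leaves[int(i)]
            for i in rng.choice(n_leaves, size=min(size, n_leaves), replace=False)
        )
        disease_id = f"{100000 + k}"
        diseases.append(Disease(disease_id=disease_id, phenotypes=frozenset(terms)))
        disease_terms[disease_id] = terms

    planted_gene = {
        d.disease_id: gene_ids[k % spec.n_genes] for k, d in enumerate(diseases)
    }

    models: list[MouseModel] = []
    for j in range(spec.n_models):
        gene_index = j % spec.n_genes
        genotype_id = f"MGI:{3000000 + j}"
        planted_for = [
            d for k, d in enumerate(diseases)
            if k % spec.n_genes == gene_index and j == gene_index
        ]
        # Planted models mirror each of their disease's phenotypes with
        # probability p_shared (a random term otherwise); decoy models draw
        # the same number of terms as a disease profile would, so that at
        # p_shared=0 planted and decoy models are statistically exchangeable
        # and profile size carries no signal.
        phenotypes: set[str] = set()
        if planted_for:
            for disease in planted_for:
                for term in disease_terms[disease.disease_id]:
                    if rng.random() < spec.p_shared:
                        phenotypes.add(mirror[term])
                    else:
                        phenotypes.add(target_leaves[int(rng.integers(0, n_leaves))])
            n_base = len(phenotypes)
        else:
            size = int(rng.integers(3, 16))
            phenotypes = {
                target_leaves[int(i)]
                for i in rng.choice(n_leaves, size=min(size, n_leaves), replace=False)
            }
            n_base = size
        for _ in range(n_base):
            if rng.random() < spec.p_noise:
                phenotypes.add(target_leaves[int(rng.integers(0, n_leaves))])
        symbol = mouse_symbols[gene_index]
        models.append(
            MouseModel(
                genotype_id=genotype_id,
                allele_symbols=(f"{symbol}<tm1Syn>",),
                gene_ids=(gene_ids[gene_index],),
                phenotypes=frozenset(sorted(phenotypes)),
            )
        )

    genotype_of_gene = {m.gene_ids[0]: m.genotype_id for m in reversed(models)}
    positives_mouse = frozenset(
        (planted_gene[d.disease_id], d.disease_id) for d in diseases
    )
    positives_human = frozenset(
        (human_symbols[gene_ids.index(g)], d) for g, d in positives_mouse
    )
    orthology_pairs = list(zip(mouse_symbols, gene_ids, human_symbols))

    files: dict[str, Path] = {}

    files["source_obo"] = out / "hp.obo"
    write_obo(source, str(files["source_obo"]))
    files["target_obo"] = out / "mp.obo"
    write_obo(target, str(files["target_obo"]))

    files["axioms"] = out / "axioms.tsv"
    with open(files["axioms"], "w", encoding="utf-8") as handle:
        handle.write("# synthetic cross-ontology axioms: left\trelation\tright\n")
        for axiom in sorted(axioms, key=lambda a: (a.left, a.right)):
            handle.write(f"{axiom.left}\tequivalent\t{axiom.right}\n")

    files["gene_pheno"] = out / "MGI_GenePheno.rpt"
    with open(files["gene_pheno"], "w", encoding="utf-8") as handle:
        handle.write("#genotype_id\tallelic_composition\tmp_id\tgene_ids\n")
        for model in models:
            composition = "/".join(model.allele_symbols * 2)
            for term in sorted(model.phenotypes):
                handle.write(
                    f"{model.genotype_id}\t{composition}\t{term}\t{','.join(model.gene_ids)}\n"
                )

    files["geno_disease"] = out / "MGI_GenoDisease.rpt"
    with open(files["geno_disease"], "w", encoding="utf-8") as handle:
        handle.write("#genotype_id\tomim_id\tgene_ids\n")
        for disease in diseases:
            gene = planted_gene[disease.disease_id]
            handle.write(
                f"{genotype_of_gene[gene]}\tOMIM:{disease.disease_id}\t{gene}\n"
            )

    files["orthology"] = out / "HMD_Human5.rpt"
    with open(files["orthology"], "w", encoding="utf-8") as handle:
        handle.write("#mouse_symbol\tmgi_id\thuman_symbol\n")
        for mouse_symbol, mgi_id, human_symbol in orthology_pairs:
            handle.write(f"{mouse_symbol}\t{mgi_id}\t{human_symbol}\n")

    files["hpo_annotations"] = out / "phenotype_annotation.tab"
    with open(files["hpo_annotations"], "w", encoding="utf-8") as handle:
        handle.write("#db\tdb_object_id\tdb_name\tqualifier\thpo_id\n")
        for disease in diseases:
            for term in sorted(disease.phenotypes):
                handle.write(
                    f"OMIM\t{disease.disease_id}\tsynthetic disease {disease.disease_id}\t\t{term}\n"
                )

    files["morbidmap"] = out / "morbidmap.txt"
    with open(files["morbidmap"], "w", encoding="utf-8") as handle:
        for disease in diseases:
            gene = planted_gene[disease.disease_id]
            index = gene_ids.index(gene)
            handle.write(
                f"Synthetic disease {_spell_index(index)}, {disease.disease_id} (3)"
                f"|{human_symbols[index]}|{600000 + index}|1p36\n"
            )

    return CorpusTruth(
        spec=spec,
        source_ontology=source,
        target_ontology=target,
        axioms=axioms,
        mirror=mirror,
        models=models,
        diseases=diseases,
        planted_gene=planted_gene,
        orthology_pairs=orthology_pairs,
        positives_mouse=positives_mouse,
        positives_human=positives_human,
        files=files,
    )
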