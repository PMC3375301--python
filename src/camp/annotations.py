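"""Readers for mouse and human annotation/association file dialects.

Covers the flat files a phenotype-based prioritization run needs:

* ``MGI_GenePheno.rpt``-style genotype→MP annotations (mouse models),
* ``MGI_GenoDisease.rpt``-style genotype→OMIM associations (mouse-side truth),
* ``HMD_Human5.rpt``-style human–mouse orthology,
* HPO annotation tab files (disease→HPO terms),
* OMIM MorbidMap (human gene–disease associations).

Column positions for the ``.rpt`` dialects are resolved from a ``#``-prefixed
header line when present, with positional fallback (report schemas drift
between snapshots). Rows that cannot be interpreted are skipped with a
logged warning rather than aborting the run; genuinely missing columns raise
:class:`AnnotationParseError`.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from collections.abc import Iterable

from .errors import AnnotationParseError, UnknownConceptError
from .ontology import Ontology

logger = logging.getLogger(__name__)

_MIM_RE = re.compile(r"\b(\d{6})\b")
_PHENE_KEY_RE = re.compile(r"\((\d)\)\s*$")


@dataclass
class MouseModel:
    """A mutant mouse genotype with its MP phenotype annotations.

    ``gene_ids`` lists all genes targeted in the mutant (MGI CURIEs); gene
    level scores aggregate over all models targeting the gene.
    """

    genotype_id: str
    allele_symbols: tuple[str, ...]
    gene_ids: tuple[str, ...]
    phenotypes: frozenset[str]


@dataclass
class Disease:
    """An OMIM disease with its HPO phenotype annotations."""

    disease_id: str
    phenotypes: frozenset[str]


@dataclass(frozen=True)
class AssociationTable:
    """Known gene–disease pairs; the positive labels for evaluation.

    ``source`` is ``"mgi"`` (mouse genes, MGI CURIEs) or ``"morbidmap"``
    (human gene symbols).
    """

    pairs: frozenset[tuple[str, str]]
    source: str


@dataclass
class OrthologyMap:
    """Many-to-many human–mouse orthology, indexed in both directions."""

    mouse_to_human: dict[str, frozenset[str]]
    human_to_mouse: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologyMap":
        """Build from (mouse MGI CURIE, human symbol) pairs."""
        m2h: dict[str, set[str]] = defaultdict(set)
        h2m: dict[str, set[str]] = defaultdict(set)
        for mouse, human in pairs:
            m2h[mouse].add(human)
            h2m[human].add(mouse)
        return cls(
            mouse_to_human={k: frozenset(v) for k, v in m2h.items()},
            human_to_mouse={k: frozenset(v) for k, v in h2m.items()},
        )

    def human_orthologs(self, mouse_gene: str) -> frozenset[str]:
        return self.mouse_to_human.get(mouse_gene, frozenset())

    def mouse_orthologs(self, human_gene: str) -> frozenset[str]:
        return self.human_to_mouse.get(human_gene, frozenset())


def _read_rows(path: str) -> tuple[list[str] | None, list[tuple[int, list[str]]]]:
    """Read a TSV; returns (header names or None, [(line number, fields)])."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if header is None:
                    header = [name.strip() for name in line.lstrip("#").split("\t")]
                continue
            rows.append((number, line.split("\t")))
    return header, rows


def _column_index(
    header: list[str] | None, name: str, fallback: int, path: str
) -> int:
    if header is None:
        return fallback
    try:
        return header.index(name)
    except ValueError as exc:
        raise AnnotationParseError(f"{path}: missing required column {name!r}") from exc


def _split_genes(field: str) -> tuple[str, ...]:
    return tuple(g.strip() for g in field.split(",") if g.strip())


def _allele_symbols(allelic_composition: str) -> tuple[str, ...]:
    symbols = []
    for part in allelic_composition.split("/"):
        part = part.strip()
        if part and part not in symbols:
            symbols.append(part)
    return tuple(symbols)


def parse_gene_pheno(path: str, ontology: Ontology | None = None) -> list[MouseModel]:
    """Parse a genotype–phenotype report into :class:`MouseModel` records.

    One model per genotype; phenotype sets are deduplicated. When ``ontology``
    is given, MP ids are resolved through it (alt_ids honoured) and rows with
    unresolvable or obsolete ids are skipped with a logged count.
    """
    header, rows = _read_rows(path)
    col = {
        name: _column_index(header, name, fallback, path)
        for fallback, name in enumerate(
            ("genotype_id", "allelic_composition", "mp_id", "gene_ids")
        )
    }
    phenotypes: dict[str, set[str]] = defaultdict(set)
    alleles: dict[str, tuple[str, ...]] = {}
    genes: dict[str, tuple[str, ...]] = {}
    skipped = 0
    for number, fields in rows:
        if len(fields) <= max(col.values()):
            raise AnnotationParseError(
                f"{path}:{number}: expected at least {max(col.values()) + 1} columns"
            )
        genotype = fields[col["genotype_id"]].strip()
        mp_id = fields[col["mp_id"]].strip()
        if ontology is not None:
            try:
                mp_id = ontology.resolve(mp_id)
                if ontology.concepts[mp_id].obsolete:
                    raise UnknownConceptError(mp_id, "obsolete")
            except UnknownConceptError:
                skipped += 1
                logger.warning("%s:%d: unresolvable MP id %r, row skipped", path, number, mp_id)
                continue
        phenotypes[genotype].add(mp_id)
        alleles.setdefault(genotype, _allele_symbols(fields[col["allelic_composition"]]))
        genes.setdefault(genotype, _split_genes(fields[col["gene_ids"]]))
    if skipped:
        logger.warning("%s: skipped %d rows with unresolvable MP ids", path, skipped)
    return [
        MouseModel(
            genotype_id=genotype,
            allele_symbols=alleles[genotype],
            gene_ids=genes[genotype],
            phenotypes=frozenset(phenotypes[genotype]),
        )
        for genotype in sorted(phenotypes)
    ]


def _normalize_mim(field: str) -> str | None:
    match = _MIM_RE.search(field)
    return match.group(1) if match else None


def parse_geno_disease(path: str) -> AssociationTable:
    """Parse genotype–disease rows into gene-level (MGI gene, OMIM id) pairs.

    Each row lists a genotype, an OMIM id, and the genes targeted in the
    mutant; the row expands to one pair per targeted gene. Rows without a
    parsable 6-digit OMIM id are skipped with a warning.
    """
    header, rows = _read_rows(path)
    col = {
        name: _column_index(header, name, fallback, path)
        for fallback, name in enumerate(("genotype_id", "omim_id", "gene_ids"))
    }
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    for number, fields in rows:
        if len(fields) <= max(col.values()):
            raise AnnotationParseError(
                f"{path}:{number}: expected at least {max(col.values()) + 1} columns"
            )
        mim = _normalize_mim(fields[col["omim_id"]])
        if mim is None:
            skipped += 1
            logger.warning("%s:%d: malformed OMIM id, row skipped", path, number)
            continue
        for gene in _split_genes(fields[col["gene_ids"]]):
            pairs.add((gene, mim))
    if skipped:
        logger.warning("%s: skipped %d rows with malformed OMIM ids", path, skipped)
    return AssociationTable(pairs=frozenset(pairs), source="mgi")


@dataclass(frozen=True)
class MorbidMapRecord:
    """One parsed MorbidMap row (before expansion to pairs)."""

    disease_mim: str
    gene_symbols: tuple[str, ...]
    phene_key: str | None
    provisional: bool


def parse_morbidmap(
    path: str, filter_confidence: bool = False
) -> AssociationTable:
    """Parse an OMIM MorbidMap file into (human gene symbol, disease MIM) pairs.

    Each line holds a disorder description (with the disease MIM number and a
    trailing mapping-confidence key ``(n)``), a comma-separated gene symbol
    list, the gene MIM and a cytoband; fields are ``|``- or tab-delimited
    (auto-detected per line). All listed symbols for a row are included.
    Confidence markers (``?`` prefix, ``{}``/``[]`` wrapping, the phene key)
    are parsed but by default not filtered; ``filter_confidence`` drops
    provisional/susceptibility/nondisease rows. Rows without a parsable
    disease MIM are skipped (count logged).
    """
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    with open(path, encoding="utf-8") as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("|") if "|" in line else line.split("\t")
            if len(fields) < 2:
                skipped += 1
                logger.warning("%s:%d: too few fields, row skipped", path, number)
                continue
            disorder = fields[0].strip()
            mim = _normalize_mim(_PHENE_KEY_RE.sub("", disorder))
            if mim is None:
                skipped += 1
                logger.warning("%s:%d: no disease MIM found, row skipped", path, number)
                continue
            provisional = disorder.startswith(("?", "{", "["))
            if filter_confidence and provisional:
                continue
            for symbol in _split_genes(fields[1]):
                pairs.add((symbol, mim))
    if skipped:
        logger.warning("%s: skipped %d rows without a disease MIM", path, skipped)
    return AssociationTable(pairs=frozenset(pairs), source="morbidmap")


def parse_hpo_annotations(path: str, ontology: Ontology | None = None) -> list[Disease]:
    """Parse an HPO annotation tab file into :class:`Disease` records.

    Columns (positional, header optional): DB, DB_Object_ID, DB_Name,
    Qualifier, HPO_ID. Rows with Qualifier ``NOT`` are excluded; HPO ids are
    resolved via alt_id when an ontology is supplied, otherwise kept verbatim;
    unresolvable ids are skipped with a warning.
    """
    header, rows = _read_rows(path)
    col = {
        name: _column_index(header, name, fallback, path)
        for fallback, name in enumerate(
            ("db", "db_object_id", "db_name", "qualifier", "hpo_id")
        )
    }
    by_disease: dict[str, set[str]] = defaultdict(set)
    skipped = 0
    for number, fields in rows:
        if len(fields) <= max(col.values()):
            raise AnnotationParseError(
                f"{path}:{number}: expected at least {max(col.values()) + 1} columns"
            )
        if fields[col["qualifier"]].strip().upper() == "NOT":
            continue
        disease_id = fields[col["db_object_id"]].strip()
        hpo_id = fields[col["hpo_id"]].strip()
        if ontology is not None:
            try:
                hpo_id = ontology.resolve(hpo_id)
                if ontology.concepts[hpo_id].obsolete:
                    raise UnknownConceptError(hpo_id, "obsolete")
            except UnknownConceptError:
                skipped += 1
                logger.warning(
                    "%s:%d: unresolvable HPO id %r, row skipped", path, number, hpo_id
                )
                continue
        by_disease[disease_id].add(hpo_id)
    if skipped:
        logger.warning("%s: skipped %d rows with unresolvable HPO ids", path, skipped)
    return [
        Disease(disease_id=disease_id, phenotypes=frozenset(by_disease[disease_id]))
        for disease_id in sorted(by_disease)
    ]


def parse_orthology(path: str) -> OrthologyMap:
    """Parse a human–mouse orthology report into an :class:`OrthologyMap`.

    Columns (header optional): mouse symbol, MGI id, human symbol. The map is
    keyed by MGI CURIE on the mouse side and symbol on the human side, and
    supports many-to-many lookup in both directions.
    """
    header, rows = _read_rows(path)
    col = {
        name: _column_index(header, name, fallback, path)
        for fallback, name in enumerate(("mouse_symbol", "mgi_id", "human_symbol"))
    }
    pairs = []
    for number, fields in rows:
        if len(fields) <= max(col.values()):
            raise AnnotationParseError(
                f"{path}:{number}: expected at least {max(col.values()) + 1} columns"
            )
        pairs.append((fields[col["mgi_id"]].strip(), fields[col["human_symbol"]].strip()))
    return OrthologyMap.from_pairs(pairs)
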