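# Methods

## Model and assumptions

The package treats a phenotype ontology as its subsumption fragment only: a
directed acyclic graph of concepts connected by `is_a` edges, with labels,
synonyms (with OBO scopes), alternate ids and obsolete flags. Other OBO
relationship types (`part_of`, regulates, …) are deliberately ignored — the
similarity measure is defined over the taxonomy, and including non-subsumption
edges would change its semantics. Multi-root ontologies are allowed as-is; no
synthetic root is inserted. Closure includes the root(s), so two non-empty
profiles in a single-rooted ontology always have similarity > 0.

Cross-ontology axioms relate *atomic* concepts: `A EquivalentTo B`,
`A SubClassOf B`, or `B SubClassOf A`. Equivalence is modeled as a pair of
directed subclass edges, which turns "equivalent to or superclass of" queries
into plain graph reachability over the union of both `is_a` hierarchies and
the axiom edges. For this axiom fragment (no conjunctions, no existential
restrictions) reachability computes exactly what an OWL reasoner would
classify, at a fraction of the machinery. The OWL-EL reasoning that produces
ontological axiom tables in the first place (over EQ definitions and bridging
anatomy ontologies) is out of scope; such tables are consumed as 3-column TSV.

Lexical matching considers concept labels and synonyms of all scopes (an
`exact_scope_only` flag restricts to EXACT synonyms). Strings are normalized
— lowercased, punctuation collapsed to single spaces — before comparison, and
two strings match when their Levenshtein distance is ≤ 1. "At most a single
mismatching character" is therefore read as one substitution, insertion or
deletion; this subsumes the plausible narrower readings. Every lexical match
is taken to assert an equivalence. Matches are only generated across the two
ontologies, never within one.

A profile translation maps each raw term through the cross mapping (dropping
unmapped terms, with a logged count — no imputation) and then re-closes the
result in the target taxonomy. Re-closing matters: the mapped sets contain
superclasses only as far as the axioms reach, while the Jaccard similarity is
defined over fully closed sets. The Jaccard index is unweighted by design;
information-content or otherwise weighted variants are not implemented.

Gene-level scores aggregate genotype-level scores by maximum over the models
targeting a gene (associations in both MGI and MorbidMap are gene–disease
pairs, and a gene is credited with its best model). Genotypes targeting
several genes credit each of them. Rankings default to fractional (mean)
ranks for ties, with dense and ordinal policies available; candidates with
equal score are ordered by id for determinism. Ranking is exposed at both
gene and genotype granularity.

## Evaluation

Known gene–disease pairs are positives; every other *scored* pair is a
negative (there is no curated true-negative set). For MorbidMap evaluation
mouse genes are lifted to human symbols through the many-to-many orthology
map; a pair is positive if any ortholog carries the association, and mouse
genes without orthologs are excluded from that evaluation only (counted).
Pairs are pooled globally across diseases into a single ROC per
configuration; AUC is computed as the Mann–Whitney statistic (ties count
1/2), which equals the trapezoidal area under the tie-aware curve. Spearman's
rank correlation compares where the same positive associations rank under two
mapping variants; when one variant ranks every positive first the coefficient
is undefined and reported as `nan`. The paired one-tailed t-test takes the
positive-association ranks of two methods as its paired quantity — an
explicit interpretation, documented as such; zero-variance differences are
flagged degenerate and assigned the sd→0 limit p-value (0 when the first
method is uniformly better, 1 otherwise).

## Synthetic corpora

`camp.synth.make_corpus` emulates the statistical shape of the MGI/OMIM/HPO
inputs without any claim of clinical realism. Two structurally isomorphic
random DAG ontologies (default 120 concepts, depth 4; level-wise parent
sampling with 1–2 parents guarantees acyclicity) stand in for HPO and MP.
Concept labels encode their index as spelled-out digit words, which keeps
distinct labels at edit distance ≥ 2, so the lexical matcher finds exactly
the planted shared-label leaf pairs (`frac_lexical`, default 0.3) and nothing
else. A fraction `frac_axiom_coverage` (default 0.9) of paired leaves gets an
ontological equivalence axiom; 0.9 reflects that merged cross-species
coverage is high but incomplete in practice.

Diseases draw 3–15 source-ontology leaves. Each disease has one planted true
gene whose model mirrors each disease phenotype across the ontology pairing
with probability `p_shared` (default 0.9) and otherwise draws a random leaf;
decoy models draw their size from the same 3–15 regime, so that at
`p_shared = 0` planted and decoy models are statistically exchangeable and
profile size carries no signal. Each base term additionally attracts a
spurious random term with probability `p_noise` (default 0.1). Association
tables (MGI- and MorbidMap-style), 1:1 orthology and all annotation files are
written in the exact dialects the parsers read; a fixed seed yields
byte-identical bundles.

What passing tests on these corpora show: the pipeline recovers planted
signal (pooled AUC ≈ 1 at the defaults, chance level when `p_shared = 0`),
parsers round-trip the dialects, and the mapping machinery behaves per its
invariants. What they do not show: performance on real HPO/MP vocabularies,
whose label distributions, annotation biases and many-to-many orthology are
richer than the generator's. Two known idealizations: the null AUC sits
slightly above 0.5 (positives are size-matched model–disease pairs, and the
Jaccard of two random closed sets is largest when the sets have similar
size), and real lexical matches are correlated with clinical specificity in
ways uniform sampling is not.

The packaged worked-example fixtures are synthetic replicas at toy scale: the
hearing-loss pair (7 + 6 concepts, exactly one lexical match) and a
Septo-Optic Dysplasia scenario (OMIM 182230 with Vax1/Gdf6/Marcks/Hesx1
models). On the toy SOD fixture the Vax1 model ranks first; the fixture
demonstrates the translation-and-ranking mechanics, not the rank order
obtained on full-scale curated data.

## Numerical and interface choices

- Closure, mapping derivation and translation are exact set/graph
  computations; no tolerances are involved. AUC/Spearman agreement with their
  closed forms is tested at 1e-12.
- OBO parsing is backed by `obonet`; a light pre-scan reports the line number
  of a malformed stanza line, and a cycle in `is_a` raises a structural error
  naming one cycle. Obsolete terms are kept for alt_id resolution but never
  parent, match, or appear in closures. Alternate ids may not collide with
  primary ids.
- Column positions in the `.rpt`/tab dialects resolve from an optional `#`
  header with positional fallback; rows that cannot be interpreted are
  skipped with logged counts, while missing columns are hard errors.
  MorbidMap confidence markers are parsed but only filtered on request.
- Empty profiles (all terms unmapped) score 0 against everything and are
  flagged rather than dropped silently.
- Default problem sizes (120-concept ontologies, 50 genes, 30 diseases, 20
  null replicates) keep a full test-plus-acceptance run in the order of
  seconds while leaving the planted-signal recovery far from the thresholds
  asserted on it.

## Known limitations

- Lexical matching is all-pairs within ±1 length buckets; fine for the
  intended fixture and corpus scales, quadratic in the worst case on two
  full 10^4-concept vocabularies.
- Stemming or fuzzier matching beyond distance 1, weighted similarity
  measures, and re-deriving ontological axioms by description-logic reasoning
  are out of scope.
- The t-test's paired quantity and the global ROC pooling are documented
  interpretations; per-disease ROC is not implemented beyond what
  `positive_ranks` enables downstream.
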