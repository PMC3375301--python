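"""Full pipeline evaluation on a seeded synthetic corpus.

Generates a corpus with planted gene-disease associations, runs the
translate -> score -> rank pipeline under the lexical, ontological and merged
mappings, and evaluates each with a pooled ROC analysis; finally compares the
lexical and ontological prioritizations with Spearman's rank correlation.
"""

import logging
import tempfile
from pathlib import Path

from camp import CorpusSpec, make_corpus, run_pipeline, spearman_positive_ranks

logging.disable(logging.WARNING)

with tempfile.TemporaryDirectory() as tmp:
    corpus_dir = Path(tmp) / "corpus"
    truth = make_corpus(CorpusSpec(seed=42), corpus_dir)
    print(
        f"Corpus: {len(truth.models)} mouse models, {len(truth.diseases)} diseases, "
        f"{len(truth.positives_mouse)} planted associations"
    )

    runs = {}
    for mode in ("lexical", "ontological", "merged"):
        runs[mode] = run_pipeline(corpus_dir, mapping_mode=mode, assoc="mgi")
        print(f"  {mode:<12} mapping: AUC = {runs[mode].roc.auc:.3f}")

    merged = runs["merged"]
    hits = sum(
        truth.planted_gene[d] in merged.rankings[d].top(5) for d in truth.planted_gene
    )
    print(f"Planted gene in top 5 (merged): {hits}/{len(truth.planted_gene)} diseases")

    # Compare prioritization variants on a noisier corpus where the positive
    # ranks actually vary (on the clean corpus every positive ranks first and
    # rank correlation is undefined).
    cmp_dir = Path(tmp) / "comparison"
    make_corpus(CorpusSpec(seed=43, p_shared=0.6, p_noise=0.3), cmp_dir)
    cmp_lex = run_pipeline(cmp_dir, mapping_mode="lexical", assoc="mgi")
    cmp_ont = run_pipeline(cmp_dir, mapping_mode="ontological", assoc="mgi")
    ranks_lex = cmp_lex.positive_ranks()
    ranks_ont = cmp_ont.positive_ranks()
    shared = sorted(set(ranks_lex) & set(ranks_ont))
    rho = spearman_positive_ranks(
        [ranks_lex[k] for k in shared], [ranks_ont[k] for k in shared]
    )
    print(f"Spearman rho of positive ranks, lexical vs ontological: {rho:.3f}")

print(
    "\nAUC is the probability that a known gene-disease pair outscores an"
    "\nunknown one; values near 1 mean the planted signal is recovered."
)
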