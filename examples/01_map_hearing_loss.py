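"""Cross-ontology mapping on the packaged hearing-loss example.

Builds the two toy hearing-loss hierarchies (an HPO-like chain and an MP-like
chain), finds the single lexical match between them, and derives the
closure-based mapping in both directions.
"""

from camp import derive_mapping, make_fig1_fixture

hpo, mp, axioms = make_fig1_fixture()

print("Lexical matches (label/synonym strings within one mismatching character):")
for axiom in sorted(axioms, key=lambda a: a.left):
    print(
        f"  {axiom.left} ({hpo.concepts[axiom.left].label!r}) "
        f"== {axiom.right} ({mp.concepts[axiom.right].label!r})"
    )

forward = derive_mapping(hpo, mp, axioms, provenance="lexical")
by_label = {c.label: c.id for c in hpo.concepts.values()}
for label in ("Hearing loss", "Progressive hearing impairment"):
    targets = sorted(mp.concepts[t].label for t in forward.table[by_label[label]])
    print(f"\nHPO {label!r} maps to {len(targets)} MP concepts:")
    for t in targets:
        print(f"  - {t}")

backward = derive_mapping(mp, hpo, axioms, provenance="lexical")
deafness = next(c.id for c in mp.concepts.values() if c.label == "deafness")
targets = sorted(hpo.concepts[t].label for t in backward.table[deafness])
print(f"\nMP 'deafness' maps to {len(targets)} HPO concepts:")
for t in targets:
    print(f"  - {t}")

print(
    "\nEach mapped set is the equivalent concept plus all of its superclasses"
    "\nin the other ontology, so subclasses inherit their ancestors' mappings."
)
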