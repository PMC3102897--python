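"""Term matching and structural subsumption over a small vaccine ontology.

Builds a toy term set with an asserted is_a hierarchy and quality
annotations, matches term synonyms in text, and infers which terms fall
under a defined class (genus plus required qualities) — e.g. a product
asserted under "vaccine using whole organism" that carries the quality
"inactivated" is inferred to be an inactivated vaccine.
"""

from condl import DefinedClass, OntologyTerm, infer_subclasses, match_terms

whole = OntologyTerm(id="whole-organism", label="vaccine using whole organism")
fluarix = OntologyTerm(
    id="Fluarix", label="Fluarix", synonyms=["influenza split vaccine"],
    parents=["whole-organism"], qualities=["inactivated"],
)
varivax = OntologyTerm(
    id="Varivax", label="Varivax", parents=["whole-organism"], qualities=["live"]
)
bcg = OntologyTerm(id="BCG", label="BCG", synonyms=["Bacillus Calmette-Guerin"])

text = "Responses to Fluarix and Bacillus Calmette-Guerin were compared."
for m in match_terms(text, [fluarix, varivax, bcg]):
    print(f"matched {m.term_id!r} as {m.matched_synonym!r} at {m.span}")

inactivated = DefinedClass(
    id="inactivated vaccine",
    genus="whole-organism",
    required_qualities=frozenset({"inactivated"}),
)
inferred = infer_subclasses([whole, fluarix, varivax, bcg], [inactivated])
print()
for term_id, classes in sorted(inferred.items()):
    print(f"{term_id:15s} inferred under: {sorted(classes) or '-'}")
# Fluarix is inferred as an inactivated vaccine because its asserted
# parent matches the genus and it carries the required quality; Varivax
# (live) and BCG (no asserted parent here) are not.
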