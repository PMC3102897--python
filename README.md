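# condl

Centrality- and ontology-based discovery of gene interaction networks
from literature-derived dependency parses.

`condl` is a Python library (plus a thin `condl` command-line tool) for
researchers who mine gene–gene interaction networks out of tagged,
dependency-parsed biomedical text and want to sharpen the result with a
domain vocabulary — the motivating case being vaccine-associated
interferon-gamma (IFNG) networks filtered with vaccine names from the
Vaccine Ontology. It covers the full chain:

1. **Candidate selection** — keep sentences with ≥ 2 dictionary-normalized
   gene mentions and ≥ 1 interaction keyword.
2. **Relation extraction** — for every gene pair, take the shortest path
   between the mentions in the dependency tree, written as the
   alternating sequence of edge labels and intermediate words
   (`nominal-subject up-regulated direct-object`). Paths are compared
   with sequence edit distance *d(p, q)* and the edit kernel

   *K(p, q) = exp(−γ · d(p, q))*

   which feeds a precomputed-kernel SVM that classifies each path as
   stating an interaction or not.
3. **Layered networks** — classified pairs build three nested undirected
   networks around a seed gene: *generic* (all sentences), *concept*
   (sentences mentioning the generic concept word, e.g. "vaccine"), and
   *concept_ontology* (sentences mentioning the word **or** any specific
   ontology term, e.g. "BCG").
4. **Centrality ranking** — degree, eigenvector, closeness
   (Wasserman–Faust scaled) and betweenness (unnormalized Brandes)
   centralities with competition ranks; the seed gene is excluded from
   the ranking.
5. **Association networks** — abstract-level gene–concept co-occurrence;
   a concept–concept network linking two concepts when they share a
   central gene; the same four centralities; and community detection by
   greedy modularity maximization
   (*Q = Σ_c (e_c/m − (d_c/2m)²)*, agglomerative merging).
6. **Ontology support** — flat term files with `|#|`-separated synonyms,
   word-boundary synonym matching, and a structural-subsumption rule
   that infers terms under defined classes (genus + required qualities,
   e.g. *"vaccine using whole organism" and (has_quality some
   inactivated)*).

A deterministic synthetic-corpus generator with exact ground-truth
bookkeeping stands in for a PubMed-scale corpus, so the whole pipeline
is testable offline.

## Worked example

```bash
python examples/01_dependency_paths_and_kernel.py
```

prints, for the packaged example sentence *"In addition, IFN-alpha
up-regulated BCG-induced IL-12 and TNF-alpha and down-regulated
BCG-induced IL-10"*:

```
IFN-alpha & IL-12: nominal-subject up-regulated direct-object
IFN-alpha & TNF-alpha: nominal-subject up-regulated direct-object IL-12 conjunct-and
IFN-alpha & IL-10: nominal-subject up-regulated conjunct-and down-regulated direct-object

edit distance between the first two paths: 2
kernel similarity exp(-0.5 * 2) = 0.3679
```

The distance 2 counts the two insertions (the word "IL-12" and the label
"conjunct-and") that transform the first path into the second; the
kernel turns it into a similarity in (0, 1] for the SVM.

```bash
python examples/02_vaccine_network_communities.py
```

builds the vaccine–vaccine network from the packaged 28-vaccine /
32-gene association table and prints:

```
vaccine-vaccine network: 28 vaccines, 259 edges

most central vaccines (degree, eigenvector, closeness, betweenness):
  BCG Vaccine       27      0.2271    1.0000       30.82
  LVS               27      0.2271    1.0000       30.82
  RTS,S/AS02A       26      0.2261    0.9643       18.32
  Dryvax            25      0.2239    0.9310       13.30
  Pneumo 23         24      0.2220    0.9000        7.65

greedy modularity: 2 communities, sizes [16, 12], Q = 0.0902
```

Both hub vaccines touch all 27 others (they share a central gene with
every vaccine), and the greedy merge splits the network into a
mostly-viral community of 16 and a mostly-bacterial community of 12.

The other examples (`03_synthetic_end_to_end.py`,
`04_ontology_inference.py`) demonstrate synthetic-corpus recovery and
ontology inference; the `condl` CLI (`condl synth`, `train`, `extract`,
`network`, `rank`, `associate`, `communities`, `fixtures export`)
exposes the same steps for shell pipelines.

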