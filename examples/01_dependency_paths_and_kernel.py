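"""Shortest dependency paths and the edit kernel on the worked example.

Builds the packaged example sentence ("In addition, IFN-alpha
up-regulated BCG-induced IL-12 and TNF-alpha and down-regulated
BCG-induced IL-10"), extracts the shortest dependency path for each
interacting gene pair, and compares two paths with the edit distance and
the exponential similarity kernel.
"""

from condl import GeneDictionary, edit_distance, normalize_mentions, shortest_path
from condl import similarity, KernelConfig
from condl import fixtures as fx

sentence = fx.worked_example_sentence()
dictionary = GeneDictionary(
    {"IFNA1": ["IFN-alpha"], "IL12B": ["IL-12"], "TNF": ["TNF-alpha"], "IL10": ["IL-10"]}
)
sentence = normalize_mentions(sentence, dictionary)
mentions = {m.surface: m for m in sentence.mentions}

print("sentence:", sentence.text)
print()
paths = {}
for a, b in [("IFN-alpha", "IL-12"), ("IFN-alpha", "TNF-alpha"), ("IFN-alpha", "IL-10")]:
    path = shortest_path(sentence, (mentions[a], mentions[b]))
    paths[(a, b)] = path
    print(f"{a} & {b}: {' '.join(path.elements)}")

p1 = paths[("IFN-alpha", "IL-12")]
p2 = paths[("IFN-alpha", "TNF-alpha")]
d = edit_distance(p1, p2)
s = similarity(p1, p2, KernelConfig(gamma=0.5))
print()
print(f"edit distance between the first two paths: {d:.0f}")
print(f"kernel similarity exp(-0.5 * {d:.0f}) = {s:.4f}")
# The distance of 2 reflects the two insertions (the intermediate word
# "IL-12" and the conjunction label) that turn one path into the other;
# the kernel maps that distance into (0, 1] for the SVM.
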