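{
 "document_id": "9607926",
 "sentence_index": 0,
 "tokens": ["In", "addition", ",", "IFN-alpha", "up-regulated", "BCG-induced", "IL-12", "and", "TNF-alpha", "and", "down-regulated", "BCG-induced", "IL-10"],
 "dep_edges": [
  [4, 3, "nominal-subject"],
  [4, 6, "direct-object"],
  [6, 8, "conjunct-and"],
  [4, 10, "conjunct-and"],
  [10, 12, "direct-object"],
  [6, 5, "adjectival-modifier"],
  [12, 11, "adjectival-modifier"],
  [4, 0, "prepositional-modifier"],
  [0, 1, "object-of-preposition"],
  [4, 2, "punctuation"],
  [6, 7, "coordination"],
  [4, 9, "coordination"]
 ],
 "mentions": [
  {"start": 3, "end": 4, "surface": "IFN-alpha"},
  {"start": 6, "end": 7, "surface": "IL-12"},
  {"start": 8, "end": 9, "surface": "TNF-alpha"},
  {"start": 12, "end": 13, "surface": "IL-10"}
 ]
}
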