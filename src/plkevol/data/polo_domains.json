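{
  "_comment": "Approximate Polo-like kinase domain boundaries in 1-based inclusive coordinates on the D. melanogaster Polo protein (576 aa): kinase domain and Polo-box domain positions follow UniProt/Pfam annotations of Plk1-family kinases; the linker is the region between them. These defaults are configuration with documented provenance, not measured values; supply your own map for a different alignment frame.",
  "kinase": [[21, 290]],
  "linker": [[291, 410]],
  "PBD": [[411, 576]],
  "PB1": [[411, 490]],
  "PB2": [[505, 576]]
}
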