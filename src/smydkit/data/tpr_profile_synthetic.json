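{
  "name": "TPR_34_synthetic",
  "description": "Synthetic 34-residue tetratricopeptide-repeat position-weight profile built around an idealised consensus repeat. Conserved small/helix-packing positions carry double weight. Constructed in-house for the fallback detector; external domain annotations always take precedence.",
  "consensus": "AEAWYNLGNAYYKQGDYDEAIEYYQKALELDPRS",
  "weights": [1, 1, 1, 2, 1, 1, 2, 2, 1, 1, 2, 1, 1, 1, 1, 1, 1, 1, 1, 2, 1, 1, 1, 2, 1, 1, 2, 1, 1, 1, 1, 2, 1, 1]
}
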