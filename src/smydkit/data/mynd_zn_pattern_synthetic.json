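{
  "name": "MYND_cross_brace_synthetic",
  "description": "Synthetic cross-brace MYND-like Zn-finger signature. Eight ligand positions in four pairs; pairs 1 and 3 bind the first Zn ion, pairs 2 and 4 the second. Ligands are cysteine, with histidine tolerated at position 7. Within-pair spacing is short and near-invariant; between-pair spacers are longer and more variable, the pair 1-2 spacer most of all. Constructed stand-in for the PROSITE MYND signature, which is not redistributable here; all bounds count residues strictly between the two ligands.",
  "position_ligands": [["C"], ["C"], ["C"], ["C"], ["C"], ["C"], ["C", "H"], ["C"]],
  "within_pair_spacers": [[2, 4], [2, 2], [2, 2], [2, 2]],
  "between_pair_spacers": [[7, 14], [4, 8], [8, 14]]
}
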