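{
  "description": "Interaction energies (kcal/mol) for the aromatic rings of ribocil stacked with FMN-riboswitch nucleobases (PDB 5C45), with the corresponding model global-minimum (maximum) stacking energies.",
  "contacts": {
    "thiophene-A48": {"e_pose": -4.9, "e_max": -6.9},
    "pyrimidine-A85": {"e_pose": -8.3, "e_max": -8.8},
    "pyrimidine-G62": {"e_pose": -4.6, "e_max": -9.6}
  },
  "central_ring_tautomers": {
    "pyrimidone-A85": -8.0,
    "hydroxypyrimidine-A85": -9.1,
    "pyrimidinone_adenine_predicted_max": -9.5
  }
}
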