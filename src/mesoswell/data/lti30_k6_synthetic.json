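{
  "label": "Lti30 (K6), synthetic representative architecture",
  "comment": "Six membrane-binding K-segments separated by five uncharged disordered segments. Residue counts are synthetic representatives spanning the 8-19 aa range reported for this protein family; override with sequence-exact values when available. Net bound-state charge inferred from electroneutrality at 0.1 mol% protein with 5 mol% monovalent anionic lipid.",
  "synthetic": true,
  "n_k_segments": 6,
  "segment_lengths_aa": [8, 11, 14, 17, 19],
  "net_positive_charge": 50
}
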