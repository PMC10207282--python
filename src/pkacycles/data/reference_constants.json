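{
  "reference_molecule": "2-imino-thiazolidinone",
  "reference_experimental_pka_water": 11.70,
  "reference_calculated_pka_mecn": 19.41,
  "tc2_best_calculated_pka_water": 12.47,
  "best_level_of_theory": "M062X/6-31G**",
  "best_solvent_model": "SMD"
}
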