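{
  "apatite": {
    "formula": {"Ca": 10, "P": 6, "O": 26, "H": 2},
    "density_g_cm3": 3.16,
    "comment": "hydroxyapatite Ca10(PO4)6(OH)2; density of the pure mineral"
  },
  "calcite": {
    "formula": {"Ca": 1, "C": 1, "O": 3},
    "density_g_cm3": 2.71
  },
  "quartz": {
    "formula": {"Si": 1, "O": 2},
    "density_g_cm3": 2.65
  }
}
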