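{
  "AMPA":     {"ligand": "[3H]-AMPA",          "L_nM": 10.0, "type": "agonist"},
  "NMDA":     {"ligand": "[3H]-MK-801",        "L_nM": 3.3,  "type": "antagonist"},
  "kainate":  {"ligand": "[3H]-kainate",       "L_nM": 9.4,  "type": "agonist"},
  "GABAA":    {"ligand": "[3H]-muscimol",      "L_nM": 7.7,  "type": "agonist"},
  "GABAB":    {"ligand": "[3H]-CGP 54626",     "L_nM": 2.0,  "type": "antagonist"},
  "GABAA/BZ": {"ligand": "[3H]-flumazenil",    "L_nM": 1.0,  "type": "antagonist"},
  "M1":       {"ligand": "[3H]-pirenzepine",   "L_nM": 1.0,  "type": "antagonist"},
  "M2":       {"ligand": "[3H]-oxotremorine-M","L_nM": 1.7,  "type": "agonist"},
  "M3":       {"ligand": "[3H]-4-DAMP",        "L_nM": 1.0,  "type": "antagonist"},
  "alpha1":   {"ligand": "[3H]-prazosin",      "L_nM": 0.2,  "type": "antagonist"},
  "alpha2":   {"ligand": "[3H]-UK 14,304",     "L_nM": 0.64, "type": "agonist"},
  "5-HT1A":   {"ligand": "[3H]-8-OH-DPAT",     "L_nM": 1.0,  "type": "agonist"},
  "5-HT2":    {"ligand": "[3H]-ketanserin",    "L_nM": 1.14, "type": "antagonist"},
  "D1":       {"ligand": "[3H]-SCH 23390",     "L_nM": 1.67, "type": "antagonist"},
  "A1":       {"ligand": "[3H]-DPCPX",         "L_nM": 1.0,  "type": "antagonist"}
}
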