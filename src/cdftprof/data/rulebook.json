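[
  {"property": "caco2", "kind": "threshold", "op": ">", "threshold": 0.90,
   "verdict_true": "high Caco-2 permeability",
   "verdict_false": "not high Caco-2 permeability",
   "near_margin": 0.2},
  {"property": "intestinal_absorption", "kind": "threshold", "op": "<", "threshold": 30.0,
   "verdict_true": "poorly absorbed",
   "verdict_false": "acceptably absorbed"},
  {"property": "skin_logkp", "kind": "threshold", "op": ">", "threshold": -2.5,
   "verdict_true": "low skin permeability",
   "verdict_false": "not low skin permeability"},
  {"property": "bbb_logbb", "kind": "band", "upper": -0.3, "lower": -1.0,
   "verdict_high": "readily crosses the blood-brain barrier",
   "verdict_mid": "intermediate brain distribution",
   "verdict_low": "poorly distributed to the brain"},
  {"property": "tpyriformis", "kind": "threshold", "op": ">", "threshold": -0.5,
   "verdict_true": "toxic to T. pyriformis",
   "verdict_false": "not toxic to T. pyriformis"},
  {"property": "cns_logps", "kind": "report", "note": "no stated CNS cutoff"},
  {"property": "vdss", "kind": "report", "note": "steady-state volume of distribution, log L/kg"},
  {"property": "fraction_unbound", "kind": "report", "note": "plasma fraction unbound"},
  {"property": "total_clearance", "kind": "report", "note": "log ml/min/kg"},
  {"property": "max_tolerated_dose", "kind": "report", "note": "log mg/kg/day, human"},
  {"property": "orat_ld50", "kind": "report", "note": "oral rat acute toxicity LD50, mol/kg"},
  {"property": "orct", "kind": "report", "note": "oral rat chronic toxicity LOAEL"},
  {"property": "pgp_substrate", "kind": "flag",
   "verdict_true": "P-glycoprotein substrate", "verdict_false": "not a P-glycoprotein substrate"},
  {"property": "pgp1_inhibitor", "kind": "flag",
   "verdict_true": "P-glycoprotein I inhibitor", "verdict_false": "not a P-glycoprotein I inhibitor"},
  {"property": "pgp2_inhibitor", "kind": "flag",
   "verdict_true": "P-glycoprotein II inhibitor", "verdict_false": "not a P-glycoprotein II inhibitor"},
  {"property": "cyp2d6_substrate", "kind": "flag",
   "verdict_true": "CYP2D6 substrate", "verdict_false": "not a CYP2D6 substrate"},
  {"property": "cyp3a4_substrate", "kind": "flag",
   "verdict_true": "CYP3A4 substrate", "verdict_false": "not a CYP3A4 substrate"},
  {"property": "cyp1a2_inhibitor", "kind": "flag",
   "verdict_true": "CYP1A2 inhibitor", "verdict_false": "not a CYP1A2 inhibitor"},
  {"property": "cyp2c19_inhibitor", "kind": "flag",
   "verdict_true": "CYP2C19 inhibitor", "verdict_false": "not a CYP2C19 inhibitor"},
  {"property": "cyp2c9_inhibitor", "kind": "flag",
   "verdict_true": "CYP2C9 inhibitor", "verdict_false": "not a CYP2C9 inhibitor"},
  {"property": "cyp2d6_inhibitor", "kind": "flag",
   "verdict_true": "CYP2D6 inhibitor", "verdict_false": "not a CYP2D6 inhibitor"},
  {"property": "cyp3a4_inhibitor", "kind": "flag",
   "verdict_true": "CYP3A4 inhibitor", "verdict_false": "not a CYP3A4 inhibitor"},
  {"property": "oct2_substrate", "kind": "flag",
   "verdict_true": "renal OCT2 substrate", "verdict_false": "not a renal OCT2 substrate"},
  {"property": "ames", "kind": "flag",
   "verdict_true": "mutagenic (AMES positive)", "verdict_false": "non-mutagenic (AMES negative)"},
  {"property": "herg1", "kind": "flag",
   "verdict_true": "hERG I inhibitor", "verdict_false": "not an hERG I inhibitor"},
  {"property": "herg2", "kind": "flag",
   "verdict_true": "hERG II inhibitor", "verdict_false": "not an hERG II inhibitor"},
  {"property": "hepatotoxicity", "kind": "flag",
   "verdict_true": "predicted hepatotoxic", "verdict_false": "not predicted hepatotoxic"},
  {"property": "skin_sensitisation", "kind": "flag",
   "verdict_true": "skin sensitiser", "verdict_false": "not a skin sensitiser"}
]
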