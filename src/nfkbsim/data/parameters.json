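{
  "description": "Nominal rate constants and conserved protein pools of the microglial TNFα–NF-κB model. Units: first-order rates 1/min, second-order rates 1/(µM min), synthesis rates µM/min, concentrations µM. Provenance codes: 'lipniacki-family' = adopted from the canonical Lipniacki-type NF-κB parameter family (time base converted from seconds to minutes); 'calibrated' = set during model construction so that the control simulation reproduces the published control-cell behaviour of this pathway in BV2 microglia (basal nuclear NF-κB near 10% of the stimulated maximum, nuclear NF-κB peak inside the first hour, total IκBα trough near 20 min with recovery by 60–90 min, transcript induction peaking at 30–60 min); 'assumed' = order-of-magnitude choice with no direct literature anchor.",
  "rates": {
    "ka":    {"value": 0.07,   "units": "1/min",      "provenance": "calibrated",        "note": "TNF-dependent IKK activation (IKKn -> IKKa); zero flux without stimulus"},
    "kp":    {"value": 0.006,  "units": "1/min",      "provenance": "assumed",           "note": "slow recovery of inactivated IKK to the neutral form (IKKi -> IKKn)"},
    "ki":    {"value": 0.2,    "units": "1/min",      "provenance": "calibrated",        "note": "spontaneous (A20-independent) inactivation of active IKK"},
    "kiA20": {"value": 0.08,   "units": "1/(uM min)", "provenance": "calibrated",        "note": "A20-dependent inactivation of active IKK; the only downstream->IKK feedback"},
    "a1":    {"value": 30.0,   "units": "1/(uM min)", "provenance": "lipniacki-family",  "note": "IkBa + NF-kB association, both compartments"},
    "d1a":   {"value": 0.006,  "units": "1/min",      "provenance": "assumed",           "note": "IkBa:NF-kB dissociation (Kd = 0.2 nM, tight complex)"},
    "kc2a":  {"value": 4.0,    "units": "1/(uM min)", "provenance": "calibrated",        "note": "IKKa-catalyzed Ser32 phosphorylation of complexed IkBa"},
    "kc1a":  {"value": 0.8,    "units": "1/(uM min)", "provenance": "assumed",           "note": "IKKa-catalyzed phosphorylation of free IkBa (5x slower than complexed)"},
    "kua1":  {"value": 6.0,    "units": "1/min",      "provenance": "assumed",           "note": "SCF/beta-TrCP E3-ligase recruitment to phospho-IkBa"},
    "kuc1":  {"value": 6.0,    "units": "1/min",      "provenance": "assumed",           "note": "poly-ubiquitination of E3-engaged IkBa"},
    "kupd":  {"value": 6.0,    "units": "1/min",      "provenance": "assumed",           "note": "proteasomal degradation of poly-ubiquitinated IkBa"},
    "kdpi":  {"value": 0.12,   "units": "1/min",      "provenance": "assumed",           "note": "constitutive degradation of every tagged IkBa intermediate"},
    "c5a":   {"value": 0.06,   "units": "1/min",      "provenance": "calibrated",        "note": "constitutive degradation of free IkBa (unstable, t1/2 ~ 12 min)"},
    "c6a":   {"value": 0.0003, "units": "1/min",      "provenance": "calibrated",        "note": "constitutive degradation of complexed IkBa (stabilized by NF-kB), frees NF-kB"},
    "i1":    {"value": 0.6,    "units": "1/min",      "provenance": "lipniacki-family",  "note": "nuclear import of free NF-kB"},
    "i1a":   {"value": 0.15,   "units": "1/min",      "provenance": "calibrated",        "note": "nuclear import of free IkBa"},
    "e1a":   {"value": 0.03,   "units": "1/min",      "provenance": "lipniacki-family",  "note": "nuclear export of free IkBa"},
    "e2a":   {"value": 0.6,    "units": "1/min",      "provenance": "lipniacki-family",  "note": "nuclear export of the IkBa:NF-kB complex"},
    "i2a":   {"value": 0.012,  "units": "1/min",      "provenance": "assumed",           "note": "nuclear import of the IkBa:NF-kB complex (structural modification)"},
    "c1a":   {"value": 1.5e-05,"units": "uM/min",     "provenance": "calibrated",        "note": "maximal NF-kB-induced transcription of IkBa mRNA"},
    "c3a":   {"value": 0.05,   "units": "1/min",      "provenance": "calibrated",        "note": "IkBa mRNA decay (t1/2 ~ 14 min)"},
    "c2a":   {"value": 30.0,   "units": "1/min",      "provenance": "lipniacki-family",  "note": "translation of IkBa mRNA"},
    "c1":    {"value": 5e-05,  "units": "uM/min",     "provenance": "calibrated",        "note": "maximal NF-kB-induced transcription of A20 mRNA"},
    "c3":    {"value": 0.05,   "units": "1/min",      "provenance": "calibrated",        "note": "A20 mRNA decay"},
    "c2":    {"value": 30.0,   "units": "1/min",      "provenance": "lipniacki-family",  "note": "translation of A20 mRNA"},
    "c5":    {"value": 0.018,  "units": "1/min",      "provenance": "lipniacki-family",  "note": "A20 protein degradation (t1/2 ~ 39 min)"},
    "Ka":    {"value": 0.02,   "units": "uM",         "provenance": "calibrated",        "note": "half-saturation of Hill-2 NF-kB-driven transcription of both target genes"}
  },
  "pools": {
    "NFkB_pool": {"value": 0.06, "units": "uM", "provenance": "lipniacki-family", "note": "total NF-kB, initialized entirely as cytoplasmic IkBa:NF-kB complex"},
    "IKKn_pool": {"value": 0.2,  "units": "uM", "provenance": "lipniacki-family", "note": "total IKK, initialized entirely as neutral IKK"}
  }
}
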