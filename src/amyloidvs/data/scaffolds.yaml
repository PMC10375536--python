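# Scaffold library for the synthetic ligand generator. Each template is a
# SMILES with two substitution slots {R1}/{R2}; substituents are small neutral
# fragments valid in an aryl-substitution context. The families span the
# recurring amyloid-ligand motifs (fused 6,5-benzoheterocycles, stilbenes,
# chalcones, flavones, aurones, bis-styryl aromatics, ...), so property and
# similarity modules see realistic chemistry.
scaffolds:
  benzothiazole:        "c1cc({R2})cc2sc(-c3ccc({R1})cc3)nc12"
  benzoxazole:          "c1cc({R2})cc2oc(-c3ccc({R1})cc3)nc12"
  benzimidazole:        "c1cc({R2})cc2[nH]c(-c3ccc({R1})cc3)nc12"
  benzofuran:           "c1cc({R2})cc2cc(-c3ccc({R1})cc3)oc12"
  indole:               "c1cc({R2})cc2cc(-c3ccc({R1})cc3)[nH]c12"
  quinoline:            "c1cc({R2})c2ncc(-c3ccc({R1})cc3)cc2c1"
  quinoxaline:          "c1cc({R2})c2nc(-c3ccc({R1})cc3)cnc2c1"
  stilbene:             "C(=C/c1ccc({R2})cc1)\\c1ccc({R1})cc1"
  chalcone:             "O=C(/C=C/c1ccc({R2})cc1)c1ccc({R1})cc1"
  flavone:              "O=c1cc(-c2ccc({R1})cc2)oc2cc({R2})ccc12"
  aurone:               "O=C1/C(=C/c2ccc({R1})cc2)Oc2cc({R2})ccc21"
  styryl_benzothiazole: "c1cc({R2})cc2sc(/C=C/c3ccc({R1})cc3)nc12"
  biphenyl:             "c1cc({R2})ccc1-c1ccc({R1})cc1"
  naphthalene:          "c1cc({R2})c2cc({R1})ccc2c1"
  benzyloxybenzene:     "C(Oc1ccc({R2})cc1)c1ccc({R1})cc1"
  diphenylamine:        "N(c1ccc({R2})cc1)c1ccc({R1})cc1"
  bis_styryl_benzene:   "C(=C/c1ccc({R2})cc1)\\c1ccc(/C=C/c2ccc({R1})cc2)cc1"
  coumarin:             "O=c1ccc2cc({R1})c({R2})cc2o1"
  carbazole:            "c1cc({R2})c2c(c1)[nH]c1ccc({R1})cc12"
  phenylthiophene:      "c1cc({R2})cc(-c2ccc(-c3ccc({R1})cc3)s2)c1"
substituents:
  - "C"
  - "CC"
  - "CCC"
  - "C(C)C"
  - "OC"
  - "OCC"
  - "N(C)C"
  - "NC"
  - "F"
  - "Cl"
  - "Br"
  - "O"
  - "C(F)(F)F"
  - "C#N"
  - "CCO"
  - "OCCO"
  - "SC"
  - "CCl"
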