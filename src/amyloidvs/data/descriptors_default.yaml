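# Default 45-descriptor panel for the affinity models, spanning three
# categories: 1D compositional, 2D topological, and 3D conformational.
# Names refer to the descriptor registry in amyloidvs.descriptors; the list
# can be overridden (e.g. replaced verbatim by a bespoke panel) via the
# `names` argument of compute_descriptors.
compositional:
  - MolWt
  - HeavyAtomCount
  - NumHeteroatoms
  - NumHDonors
  - NumHAcceptors
  - NumRotatableBonds
  - FractionCSP3
  - NHOHCount
  - NOCount
  - MolLogP
  - MolMR
  - NumAromaticHeterocycles
  - NumAromaticCarbocycles
topological:
  - TPSA
  - LabuteASA
  - BalabanJ
  - BertzCT
  - Chi0v
  - Chi1v
  - Chi2v
  - Chi3v
  - Chi4v
  - HallKierAlpha
  - Kappa1
  - Kappa2
  - Kappa3
  - NumAromaticRings
  - NumAliphaticRings
  - NumSaturatedRings
  - RingCount
  - NumAliphaticCarbocycles
  - NumAliphaticHeterocycles
  - MaxPartialCharge
  - MinPartialCharge
  - AliphaticChainCount
conformational:
  - Asphericity
  - Eccentricity
  - InertialShapeFactor
  - NPR1
  - NPR2
  - PMI1
  - PMI2
  - PMI3
  - RadiusOfGyration
  - SpherocityIndex
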