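# Synthetic stand-in list of 49 hand-picked RDKit physico-chemical
# descriptors covering the common property families (size, lipophilicity,
# polarity, H-bonding, ring composition, topology/shape, charge). It is a
# constructed default, not a published reference list; supply your own
# selection to override it, or pass selection=None to use the automatic
# |Pearson| > 0.7 correlation-pruning mode instead.
descriptors:
  - MolWt
  - MolLogP
  - MolMR
  - TPSA
  - LabuteASA
  - qed
  - NumHAcceptors
  - NumHDonors
  - NumRotatableBonds
  - NumHeteroatoms
  - HeavyAtomCount
  - NHOHCount
  - NOCount
  - NumValenceElectrons
  - RingCount
  - NumAromaticRings
  - NumAliphaticRings
  - NumSaturatedRings
  - NumAromaticCarbocycles
  - NumAromaticHeterocycles
  - NumSaturatedCarbocycles
  - NumSaturatedHeterocycles
  - NumAliphaticCarbocycles
  - NumAliphaticHeterocycles
  - FractionCSP3
  - BalabanJ
  - BertzCT
  - HallKierAlpha
  - Chi0
  - Chi1
  - Chi0v
  - Chi1v
  - Chi2v
  - Chi3v
  - Chi4v
  - Kappa1
  - Kappa2
  - Kappa3
  - MaxPartialCharge
  - MinPartialCharge
  - MaxAbsPartialCharge
  - MinAbsPartialCharge
  - PEOE_VSA1
  - PEOE_VSA2
  - SMR_VSA1
  - SlogP_VSA1
  - SlogP_VSA2
  - EState_VSA1
  - VSA_EState1
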