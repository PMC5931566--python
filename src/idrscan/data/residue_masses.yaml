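# Average residue masses (Da) of amino-acid residues in a peptide chain
# (i.e. monomer minus water), plus the mass of one water molecule.  A chain's
# molecular weight is the sum of its residue masses plus one water.
water: 18.01524
residues:
  A: 71.0788
  C: 103.1388
  D: 115.0886
  E: 129.1155
  F: 147.1766
  G: 57.0519
  H: 137.1411
  I: 113.1594
  K: 128.1741
  L: 113.1594
  M: 131.1926
  N: 114.1038
  P: 97.1167
  Q: 128.1307
  R: 156.1875
  S: 87.0782
  T: 101.1051
  V: 99.1326
  W: 186.2132
  Y: 163.1760
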