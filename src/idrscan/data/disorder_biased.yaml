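# Default synthetic-proteome design ("disorder-biased").
#
# Emulates a heat-resistant proteome enriched in intrinsically disordered
# regions: each protein is an ordered, globular-composition backbone with
# 1-2 planted disordered regions drawn from a disorder-biased composition.
# The disordered composition is qualitatively biased the way disordered
# sequence sets are relative to globular ones: enriched in E, K, G, A, S, P
# and depleted in C, W, F, Y and the branched hydrophobics I, L, V.  With
# these settings planted disorder averages about 20% of residues per
# proteome, the level reported for experimentally enriched IDP fractions.
n_proteins: 150
length_min: 200
length_max: 600
regions_min: 1
regions_max: 2
region_length_min: 30
region_length_max: 80
seed: 2018
ordered_composition:
  A: 0.09
  C: 0.02
  D: 0.04
  E: 0.04
  F: 0.06
  G: 0.08
  H: 0.02
  I: 0.09
  K: 0.04
  L: 0.12
  M: 0.03
  N: 0.03
  P: 0.03
  Q: 0.03
  R: 0.04
  S: 0.05
  T: 0.05
  V: 0.08
  W: 0.02
  Y: 0.04
disordered_composition:
  A: 0.10
  C: 0.005
  D: 0.07
  E: 0.15
  F: 0.002
  G: 0.13
  H: 0.02
  I: 0.002
  K: 0.13
  L: 0.003
  M: 0.002
  N: 0.04
  P: 0.09
  Q: 0.07
  R: 0.05
  S: 0.09
  T: 0.04
  V: 0.003
  W: 0.001
  Y: 0.002
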