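# Default pKa table for theoretical-pI computation (Bjellqvist-style values
# as used by common proteomics servers).  Edit or replace to use another
# convention; keys: n_term, c_term, and ionizable side chains.
n_term: 7.5
c_term: 3.55
side_chains:
  D: 4.05
  E: 4.45
  H: 5.98
  C: 9.0
  Y: 10.0
  K: 10.0
  R: 12.0
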