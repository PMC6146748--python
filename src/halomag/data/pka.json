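{
  "comment": "Default pKa values for ionizable groups (editable). Basic groups: N-terminus, Lys, Arg, His; acidic groups: C-terminus, Asp, Glu, Cys, Tyr.",
  "n_term": 8.6,
  "c_term": 3.6,
  "K": 10.8,
  "R": 12.5,
  "H": 6.5,
  "D": 3.9,
  "E": 4.1,
  "C": 8.5,
  "Y": 10.1
}
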