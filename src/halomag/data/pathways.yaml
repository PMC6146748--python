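# Default KO-marker pathway definitions.
#
# Only four KO ids are anchored in the study text: acsB (K14138,
# bacterial-type CODH/ACS), cdhC (K00193, archaeal-type), nrfA/TvNiR
# (K03385) and PRK (K00855). Every other membership below is editable
# configuration assembled from the corresponding KEGG modules (noted per
# entry), not an assertion about the source study.
pathways:
  codh_acs_bacterial:
    name: CODH/ACS, bacterial type (acsB)
    required: [K14138]          # acetyl-CoA synthase beta subunit
    optional: []
  codh_acs_archaeal:
    name: CODH/ACS, archaeal type (cdhC)
    required: [K00193]          # ACDS complex beta subunit
    optional: []
  wl_eastern:
    name: Wood-Ljungdahl eastern (methyl/tetrahydrofolate) branch
    # KEGG M00377 eastern-branch steps: fdh, fhs, folD, metF
    required: [K05299, K01938, K01491, K00297]
    optional: [K15023, K22015]
    presence_threshold: 0.75
  emp_glycolysis:
    name: Embden-Meyerhof-Parnas glycolysis
    # KEGG M00001 core payoff + preparatory steps
    required: [K00844, K01810, K00850, K01623, K01803, K00134, K00927, K01834, K01689, K00873]
    optional: [K00845, K01624, K15633]
    presence_threshold: 0.8
  pfor:
    name: pyruvate:ferredoxin oxidoreductase
    # KEGG K03737 single-subunit or K00169-K00172 four-subunit complex
    required: [K03737]
    optional: [K00169, K00170, K00171, K00172]
  pta_ack:
    name: acetate interconversion (pta + ack)
    required: [K00625, K00925]  # phosphotransacetylase, acetate kinase
    optional: []
  nrfA:
    name: cytochrome c nitrite reductase (nrfA/TvNiR)
    required: [K03385]
    optional: []
  prk:
    name: phosphoribulokinase (PRK)
    required: [K00855]
    optional: []
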