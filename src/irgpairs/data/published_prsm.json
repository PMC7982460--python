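{
  "pairs": [
    ["APBB1IP", "SLA", 0.36],
    ["SIGLEC10", "KLRB1", 0.24],
    ["NFAM1", "SLA", 0.22],
    ["FAM78A", "SIRPG", 0.12],
    ["FAM78A", "CIITA", 0.33],
    ["IL2RB", "ODF3B", -0.46],
    ["DOCK2", "CXCR6", 0.20],
    ["ARHGAP25", "SLA", 0.23],
    ["SLA", "TAGAP", 0.57],
    ["SLA", "CXCL13", 0.05],
    ["RHOH", "TIGIT", 0.07],
    ["TIGIT", "APOBEC3H", -0.10],
    ["TRIM22", "SLFN5", -0.29],
    ["PPP1R16B", "GZMM", -0.23],
    ["LY9", "CLECL1", 0.46],
    ["CXCL13", "CD7", -0.18]
  ],
  "cutoff": 0.968,
  "provenance": "Published 16-pair immune-related gene-pair prognostic risk scoring model for colon adenocarcinoma (model group: TCGA COAD, left- vs right-sided contrast); dichotomization cutoff taken from the 5-year time-dependent ROC. Pair orientation is (IRG1, IRG2) as published; the indicator is 1 when IRG1 expression exceeds IRG2 within a sample."
}
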