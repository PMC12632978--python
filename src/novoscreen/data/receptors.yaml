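# Canonical pSTAT pathway weights per receptor chain.
#
# These are editable configuration, not measured data: textbook pathway
# assignments for the cytokine receptor chains (e.g. IL4Ra -> pSTAT6,
# IL7Ra -> pSTAT5, gp130/IL21Ra -> pSTAT3, IFNAR/IFNLR -> pSTAT1,
# IL12Rb1 -> pSTAT4). Non-cytokine receptors (TNF family, checkpoints,
# growth-factor RTKs) carry zero vectors: they do not signal through STATs
# in this model. Each vector must have entries in [0,1] summing to <= 1.
canonical_stats:
  gammac:  {pSTAT5: 0.70, pSTAT3: 0.15}
  betac:   {pSTAT5: 0.90}
  gp130:   {pSTAT3: 0.85, pSTAT1: 0.05}
  IL10Rb:  {pSTAT3: 0.80}
  IL4Ra:   {pSTAT6: 0.90}
  IL2Rb:   {pSTAT5: 0.90}
  IL7Ra:   {pSTAT5: 0.90}
  TSLPR:   {pSTAT5: 0.85}
  IL21Ra:  {pSTAT3: 0.70, pSTAT1: 0.10, pSTAT5: 0.10}
  IL10Ra:  {pSTAT3: 0.90}
  IL12Rb1: {pSTAT4: 0.90}
  IL23Ra:  {pSTAT3: 0.80}
  IFNAR1:  {pSTAT1: 0.20}
  IFNAR2:  {pSTAT1: 0.80, pSTAT3: 0.10}
  IFNLR:   {pSTAT1: 0.80, pSTAT3: 0.10}
  IL17Ra:  {}
  OX40:    {}
  41BB:    {}
  TNFR1:   {}
  TNFR2:   {}
  CTLA4:   {}
  PDL1:    {}
  cKit:    {}
  IGF1R:   {}
  HER2:    {}
  FGFR:    {}
  EGFR:    {}
  BMPR2:   {}
  ActRII:  {}
  INSR:    {}
  TrkA:    {}
  TGFbR2:  {}
  ALK1:    {}
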