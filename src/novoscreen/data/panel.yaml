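# Default cell panel for the synthetic screen generator.
#
# Six PBMC populations plus a monocytic-line context ("U937_like") used for
# knockout experiments. receptor_density values are surface copies per cell
# and are plausibility-scale configuration, not measurements: common chains
# (gammac, betac, gp130, IL10Rb) are broadly expressed, private chains are
# restricted to their canonical lineages, and non-cytokine receptors (TNF
# family, checkpoints, growth-factor RTKs) are present at low but functional
# levels on selected subsets. IFNLR is absent from PBMCs. baseline_mfi is the
# unstimulated per-pathway fluorescence level (arbitrary MFI units).
cell_types:
  T_CD4:
    receptor_density: {
      gammac: 2000, betac: 200, gp130: 1500, IL10Rb: 1000,
      IL7Ra: 1500, IL4Ra: 300, IL2Rb: 400, IL21Ra: 600, IL10Ra: 300,
      IL12Rb1: 400, IL23Ra: 300, TSLPR: 100, IFNAR1: 800, IFNAR2: 600,
      IFNLR: 0, IL17Ra: 400,
      OX40: 300, 41BB: 100, TNFR1: 500, TNFR2: 400, CTLA4: 300, PDL1: 100,
      cKit: 0, IGF1R: 300, HER2: 0, FGFR: 100, EGFR: 100, BMPR2: 300,
      ActRII: 300, INSR: 400, TrkA: 300, TGFbR2: 600, ALK1: 0 }
    baseline_mfi: {pSTAT1: 1200, pSTAT3: 1500, pSTAT4: 900, pSTAT5: 1800, pSTAT6: 1000}
  T_CD8:
    receptor_density: {
      gammac: 2000, betac: 200, gp130: 1400, IL10Rb: 1000,
      IL7Ra: 1400, IL4Ra: 200, IL2Rb: 900, IL21Ra: 600, IL10Ra: 300,
      IL12Rb1: 500, IL23Ra: 200, TSLPR: 100, IFNAR1: 800, IFNAR2: 600,
      IFNLR: 0, IL17Ra: 300,
      OX40: 200, 41BB: 300, TNFR1: 500, TNFR2: 400, CTLA4: 300, PDL1: 100,
      cKit: 0, IGF1R: 300, HER2: 0, FGFR: 100, EGFR: 100, BMPR2: 300,
      ActRII: 300, INSR: 400, TrkA: 200, TGFbR2: 600, ALK1: 0 }
    baseline_mfi: {pSTAT1: 1200, pSTAT3: 1400, pSTAT4: 1000, pSTAT5: 1700, pSTAT6: 950}
  NK:
    receptor_density: {
      gammac: 1500, betac: 500, gp130: 800, IL10Rb: 800,
      IL7Ra: 300, IL4Ra: 100, IL2Rb: 1500, IL21Ra: 400, IL10Ra: 200,
      IL12Rb1: 600, IL23Ra: 100, TSLPR: 0, IFNAR1: 800, IFNAR2: 600,
      IFNLR: 0, IL17Ra: 200,
      OX40: 100, 41BB: 200, TNFR1: 400, TNFR2: 500, CTLA4: 0, PDL1: 100,
      cKit: 100, IGF1R: 300, HER2: 0, FGFR: 100, EGFR: 0, BMPR2: 300,
      ActRII: 300, INSR: 300, TrkA: 100, TGFbR2: 500, ALK1: 0 }
    baseline_mfi: {pSTAT1: 1100, pSTAT3: 1300, pSTAT4: 1100, pSTAT5: 1600, pSTAT6: 900}
  B:
    receptor_density: {
      gammac: 1200, betac: 300, gp130: 1000, IL10Rb: 900,
      IL7Ra: 100, IL4Ra: 800, IL2Rb: 200, IL21Ra: 800, IL10Ra: 400,
      IL12Rb1: 200, IL23Ra: 100, TSLPR: 200, IFNAR1: 900, IFNAR2: 700,
      IFNLR: 0, IL17Ra: 200,
      OX40: 0, 41BB: 0, TNFR1: 400, TNFR2: 300, CTLA4: 100, PDL1: 200,
      cKit: 0, IGF1R: 300, HER2: 0, FGFR: 100, EGFR: 0, BMPR2: 200,
      ActRII: 200, INSR: 300, TrkA: 100, TGFbR2: 500, ALK1: 0 }
    baseline_mfi: {pSTAT1: 1300, pSTAT3: 1600, pSTAT4: 800, pSTAT5: 1500, pSTAT6: 1100}
  monocyte:
    receptor_density: {
      gammac: 800, betac: 2000, gp130: 1600, IL10Rb: 1200,
      IL7Ra: 100, IL4Ra: 500, IL2Rb: 100, IL21Ra: 200, IL10Ra: 1200,
      IL12Rb1: 300, IL23Ra: 200, TSLPR: 400, IFNAR1: 900, IFNAR2: 700,
      IFNLR: 0, IL17Ra: 500,
      OX40: 0, 41BB: 0, TNFR1: 700, TNFR2: 600, CTLA4: 0, PDL1: 400,
      cKit: 100, IGF1R: 400, HER2: 100, FGFR: 300, EGFR: 400, BMPR2: 400,
      ActRII: 400, INSR: 500, TrkA: 400, TGFbR2: 700, ALK1: 100 }
    baseline_mfi: {pSTAT1: 1400, pSTAT3: 1700, pSTAT4: 700, pSTAT5: 1300, pSTAT6: 1200}
  DC:
    receptor_density: {
      gammac: 800, betac: 1500, gp130: 1400, IL10Rb: 1000,
      IL7Ra: 200, IL4Ra: 600, IL2Rb: 100, IL21Ra: 400, IL10Ra: 600,
      IL12Rb1: 300, IL23Ra: 200, TSLPR: 800, IFNAR1: 900, IFNAR2: 700,
      IFNLR: 0, IL17Ra: 400,
      OX40: 0, 41BB: 100, TNFR1: 600, TNFR2: 500, CTLA4: 0, PDL1: 400,
      cKit: 100, IGF1R: 300, HER2: 100, FGFR: 200, EGFR: 300, BMPR2: 300,
      ActRII: 300, INSR: 400, TrkA: 300, TGFbR2: 600, ALK1: 100 }
    baseline_mfi: {pSTAT1: 1350, pSTAT3: 1650, pSTAT4: 750, pSTAT5: 1250, pSTAT6: 1150}
  U937_like:
    receptor_density: {
      gammac: 1500, betac: 1500, gp130: 1500, IL10Rb: 1200,
      IL7Ra: 1200, IL4Ra: 800, IL2Rb: 600, IL21Ra: 1200, IL10Ra: 800,
      IL12Rb1: 400, IL23Ra: 300, TSLPR: 400, IFNAR1: 1500, IFNAR2: 1000,
      IFNLR: 0, IL17Ra: 400,
      OX40: 0, 41BB: 0, TNFR1: 600, TNFR2: 500, CTLA4: 0, PDL1: 300,
      cKit: 200, IGF1R: 400, HER2: 100, FGFR: 300, EGFR: 400, BMPR2: 400,
      ActRII: 400, INSR: 500, TrkA: 400, TGFbR2: 700, ALK1: 100 }
    baseline_mfi: {pSTAT1: 1300, pSTAT3: 1600, pSTAT4: 800, pSTAT5: 1400, pSTAT6: 1100}

donors:
  n: 3
  noise_cv: 0.15          # well-level multiplicative lognormal CV
  density_sigma: 0.30     # lognormal sigma of per-donor receptor-density multipliers

screen:
  dose_nM: 250.0          # single-point screen dose
  n_control_reps: 3       # unstimulated controls per donor x cell x pathway
  stat5_leak: 0.15        # pSTAT5 leak weight for flexible (non-rigid) constructs

# Natural-cytokine positive controls (receptor pair engaged by each), run
# alongside the library in every donor x cell type. Strata where even the
# best natural cytokine responds weakly get an escalated SEM cutoff.
natural_cytokines:
  IL2:   [IL2Rb, gammac]
  IL4:   [IL4Ra, gammac]
  IL7:   [IL7Ra, gammac]
  IL10:  [IL10Ra, IL10Rb]
  IL21:  [IL21Ra, gammac]
  IFNa:  [IFNAR1, IFNAR2]
  IL12:  [IL12Rb1, IL12Rb1]
  GMCSF: [betac, betac]
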