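# 68 immunomodulator genes (immune checkpoints, co-stimulators and related
# modulators) with a coarse functional annotation: inhibitory / stimulatory /
# na (not established).  Editable default list; only a subset of members is
# fixed by the biology (LAG3, PDCD1, BTLA, CTLA4, TIGIT, CD28, CD27, ICOS,
# CD40LG, CD274, TNFRSF9, CD276, VEGFA, KIR2DL3 ...), the remainder is a
# conventional checkpoint/co-stimulator selection.
genes:
  LAG3: inhibitory
  PDCD1: inhibitory
  BTLA: inhibitory
  CTLA4: inhibitory
  TIGIT: inhibitory
  HAVCR2: inhibitory
  VSIR: inhibitory
  ADORA2A: inhibitory
  IDO1: inhibitory
  IDO2: inhibitory
  CD274: inhibitory
  PDCD1LG2: inhibitory
  CD276: inhibitory
  VTCN1: inhibitory
  HHLA2: na
  KIR2DL3: inhibitory
  KIR2DL1: inhibitory
  KIR3DL1: inhibitory
  LGALS9: inhibitory
  CEACAM1: inhibitory
  PVR: na
  NECTIN2: na
  CD47: inhibitory
  SIRPA: inhibitory
  NT5E: inhibitory
  ENTPD1: inhibitory
  VEGFA: inhibitory
  TNFRSF13B: na
  TNFSF13B: stimulatory
  TNFRSF13C: stimulatory
  CD28: stimulatory
  CD27: stimulatory
  CD70: stimulatory
  ICOS: stimulatory
  ICOSLG: stimulatory
  CD40: stimulatory
  CD40LG: stimulatory
  CD80: stimulatory
  CD86: stimulatory
  TNFRSF4: stimulatory
  TNFSF4: stimulatory
  TNFRSF9: stimulatory
  TNFRSF18: stimulatory
  TNFSF18: stimulatory
  TNFRSF14: stimulatory
  TNFSF14: stimulatory
  TNFRSF8: na
  TNFSF8: na
  TNFRSF25: stimulatory
  TNFSF15: na
  TMIGD2: stimulatory
  BTN3A1: na
  BTN3A2: na
  BTN2A1: na
  CD244: na
  CD226: stimulatory
  CD48: na
  CD58: stimulatory
  SLAMF1: na
  CD200: inhibitory
  CD200R1: inhibitory
  CD38: na
  CD44: na
  CD69: na
  ULBP1: stimulatory
  MICA: stimulatory
  MICB: stimulatory
  HLA-G: inhibitory
# Modulators the cold (adaptive-) clusters over-express; all other
# modulators co-elevate with the hot clusters.
cold_elevated: [CD274, TNFRSF9, VEGFA, CD276, KIR2DL3]
# RIG-I-like receptor and type I interferon pathway genes associated with
# long survival; profiled alongside the modulators in cluster mean profiles.
pathway_genes: [IFIH1, DDX58, ISG15, ISG20, IRF7]
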