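# 74-gene panel used for the unsupervised gene clustering that stratifies
# patients into hot/cold x innate+/- groups.  It comprises the 60 cell-type
# marker genes, the 6 cytotoxic-composite genes and 8 additional immune
# genes.  The A/B block annotation records which genes the adaptive+cytotoxic
# (A) versus innate+T (B) expression programme drives; the synthetic-cohort
# generator uses it as ground truth and the gene-partition labelling step
# uses only the seed cell types, never this annotation.
cluster_A:  # adaptive + cytotoxic programme (hot axis): B, T, CD8, Th1, NK, cytotoxic
  [MS4A1, CD19, CD79A, CD79B, TNFRSF17, CD22, BLK,
   CD8A, CD8B, GZMM,
   CD3D, CD3E, CD3G, CD2, CD6, CD5,
   TBX21, IFNG, CTLA4, IL12RB2, STAT4,
   NCR1, NCR3, XCL1, XCL2, KLRD1,
   GZMA, GZMB, PRF1, GNLY, KLRK1, NKG7,
   CXCL9, CXCL10, GZMH, TRAT1]
cluster_B:  # innate + other T programme (innate axis): Treg, Tgd, Tem, Tfh, DC, macrophage, neutrophil, mast
  [FOXP3, IKZF2, CCR8,
   TRGC1, TRDC, CD160,
   EOMES, GZMK, CXCR3,
   CXCL13, CXCR5,
   ITGAX, CD1C, CLEC4C, NRP1, FCER1A, BATF3,
   CD68, CD163, MSR1, MRC1, CSF1R, MARCO,
   FCGR3B, CSF3R, CEACAM8, S100A12, FPR1, CXCR2,
   TPSAB1, CPA3, MS4A2, KIT, HDC,
   IL1B, CXCL8, TLR2, TREM1]
# Cell types anchoring the "A" (adaptive/cytotoxic) label of the gene
# partition; their markers act as seeds for deterministic labelling.
seed_cell_types: [CD8 T cells, NK cells, B cells]
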