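# Default immune cell-type marker panel: 13 cell populations, 60 marker genes.
# Each marker is specific to a single cell type within the panel.  The lists
# are editable defaults drawn from standard immune-profiling marker sets, not
# fixed claims; swap in your own panel file with the same layout.
reference_gene: PTPRC
cell_types:
  B cells: [MS4A1, CD19, CD79A, CD79B, TNFRSF17, CD22, BLK]
  CD8 T cells: [CD8A, CD8B, GZMM]
  T cells: [CD3D, CD3E, CD3G, CD2, CD6, CD5]
  Th1: [TBX21, IFNG, CTLA4, IL12RB2, STAT4]
  NK cells: [NCR1, NCR3, XCL1, XCL2, KLRD1]
  Treg: [FOXP3, IKZF2, CCR8]
  Tgd: [TRGC1, TRDC, CD160]
  Tem: [EOMES, GZMK, CXCR3]
  Tfh: [CXCL13, CXCR5]
  DC: [ITGAX, CD1C, CLEC4C, NRP1, FCER1A, BATF3]
  Macrophages: [CD68, CD163, MSR1, MRC1, CSF1R, MARCO]
  Neutrophils: [FCGR3B, CSF3R, CEACAM8, S100A12, FPR1, CXCR2]
  Mast cells: [TPSAB1, CPA3, MS4A2, KIT, HDC]
# Shared highly expressed genes of NK / CD8 T / Tgd cells defining the
# cytotoxic composite score (not cell-type specific markers).
cytotoxic_genes: [GZMA, GZMB, PRF1, GNLY, KLRK1, NKG7]
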