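# Example marker lists for microenvironment cell-population metagenes and
# T-helper cytokine signatures.  Each score is the mean log2 expression of
# the listed markers; lists are configuration data and freely replaceable.
t_cells: [CD3D, CD3E, CD3G, CD2, CD5, TRAC]
cytotoxic_lymphocytes: [GZMA, GZMB, PRF1, KLRD1, GNLY]
nk_cells: [NCR1, KIR2DL1, KLRB1, NKG7]
b_lineage: [CD19, MS4A1, CD79A, CD79B, IGKC]
monocytic_lineage: [CD14, CD68, CSF1R, ITGAM, LYZ]
neutrophils: [FCGR3B, CSF3R, S100A8, S100A9]
endothelial_cells: [PECAM1, VWF, CDH5, KDR]
fibroblasts: [COL1A1, COL3A1, ACTA2, PDGFRB, FAP]
th1_cytokines: [IFNG, TNF, IL2, LTA]
th2_cytokines: [IL4, IL5, IL13, IL10]
th17_cytokines: [IL17A, IL17F, IL21, IL22]
treg: [FOXP3]
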