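# Default 72-gene panel: 50 tumor (subtype) genes, 17 immune genes, 5 housekeeping genes.
#
# The tumor list merges the nearest-centroid intrinsic-subtype predictor genes with the
# five additional genes the 21-gene recurrence score requires (AURKA, CTSV, GSTM1, CD68,
# SCUBE2), so both scores are computable from a single targeted panel.
# The immune list is a conventional T-cell / cytotoxicity / checkpoint panel; the score
# machinery is agnostic to the exact identities, which are expected to be overridden for
# any concrete assay.
subtype_genes:
  - ANLN
  - AURKA
  - BAG1
  - BCL2
  - BIRC5
  - CCNB1
  - CCNE1
  - CD68
  - CDC20
  - CDC6
  - CDH3
  - CENPF
  - CEP55
  - CTSV
  - EGFR
  - ERBB2
  - ESR1
  - EXO1
  - FGFR4
  - FOXA1
  - FOXC1
  - GRB7
  - GSTM1
  - KIF2C
  - KRT14
  - KRT17
  - KRT5
  - MAPT
  - MDM2
  - MELK
  - MIA
  - MKI67
  - MLPH
  - MMP11
  - MYBL2
  - MYC
  - NAT1
  - NDC80
  - NUF2
  - ORC6
  - PGR
  - PHGDH
  - PTTG1
  - RRM2
  - SCUBE2
  - SFRP1
  - SLC39A6
  - TYMS
  - UBE2C
  - UBE2T
immune_genes:
  - CD2
  - CD3D
  - CD4
  - CD8A
  - CD52
  - CD274
  - CTLA4
  - CXCL9
  - CXCL13
  - FOXP3
  - GZMA
  - GZMB
  - IDO1
  - IFNG
  - LAG3
  - PDCD1
  - PRF1
housekeeping_genes:
  - ACTB
  - GAPDH
  - GUSB
  - RPLP0
  - TFRC
# 11-gene proliferation subset used by the proliferation-weighted risk-of-recurrence score.
proliferation_genes:
  - BIRC5
  - CCNB1
  - CDC20
  - CEP55
  - MKI67
  - NDC80
  - NUF2
  - PTTG1
  - RRM2
  - TYMS
  - UBE2C
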