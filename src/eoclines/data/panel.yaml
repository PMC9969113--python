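# Characteristic gene panel for the five EOC histological subtypes.
# `characteristic` lists the genes whose alteration is diagnostic of each
# subtype; `panel` is the full set of commonly altered ovarian-cancer driver
# and tumor-suppressor genes summarized per putative subtype. Edit or replace
# via configuration; the pipeline never assumes a fixed panel size.
characteristic:
  HGSOC: [TP53, BRCA1, BRCA2]
  CCOC: [ARID1A, PIK3CA]
  ENOC: [ARID1A, PIK3CA, KRAS, PTEN, CTNNB1]
  MOC: [KRAS, NRAS, ERBB2, CDKN2A]
  LGSOC: [BRAF, KRAS, NRAS]
panel:
  - TP53
  - BRCA1
  - BRCA2
  - ARID1A
  - PIK3CA
  - KRAS
  - NRAS
  - BRAF
  - ERBB2
  - CDKN2A
  - PTEN
  - CTNNB1
  - SMARCA4
  - MYC
  - CDK12
  - RB1
  - PIK3R1
  - MET
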