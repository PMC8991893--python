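pathway	gene
DDR_HRR	BRCA1
DDR_HRR	BRCA2
DDR_HRR	PALB2
DDR_HRR	RAD51
DDR_HRR	ATM
DDR_CHECKPOINT	ATM
DDR_CHECKPOINT	ATR
DDR_CHECKPOINT	CHEK2
DDR_CHECKPOINT	TP53
RAS_SIGNALLING	KRAS
RAS_SIGNALLING	NRAS
RAS_SIGNALLING	HRAS
RAS_SIGNALLING	EGFR
RAS_SIGNALLING	ERBB2
CELL_CYCLE	CDKN2A
CELL_CYCLE	TP53
CELL_CYCLE	RNF43
TGFB_SIGNALLING	SMAD4
TGFB_SIGNALLING	TP63
CHROMATIN	KMT2D
CHROMATIN	PBRM1
METABOLISM	IDH1
METABOLISM	IDH2
METABOLISM	MTOR
FANCONI	FANCA
FANCONI	BRCA2
FANCONI	PALB2
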