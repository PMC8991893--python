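gene	gene_class	therapy
KRAS	PDAC-driver	.
TP53	PDAC-driver	.
SMAD4	PDAC-driver	.
CDKN2A	PDAC-driver	.
NRAS	RAS-family	.
HRAS	RAS-family	.
BRCA1	DDR-biomarker	PARPi/platinum
BRCA2	DDR-biomarker	PARPi/platinum
PALB2	DDR-biomarker	PARPi/platinum
ATM	DDR-pathway	.
ATR	DDR-pathway	.
CHEK2	DDR-pathway	.
RAD51	DDR-pathway	.
FANCA	DDR-pathway	.
MTOR	other-driver	.
ERBB2	other-driver	anti-ERBB2
EGFR	other-driver	.
PBRM1	other-driver	.
KMT2D	other-driver	.
RNF43	other-driver	.
IDH1	other-driver	.
IDH2	other-driver	.
TP63	other-driver	.
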