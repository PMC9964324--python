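CPI_positive	cuproptosis promoters (lipoic-acid pathway / lipoylated TCA-cycle components), printed variant	PDX1	LIAS	LIPT1	DLD	DLAT	PDHA1	PDHB
CPI_negative	cuproptosis suppressors	MTF1	GLS	CDKN2A
CPI_positive_FDX1_variant	cuproptosis promoters with FDX1 in place of PDX1, matching the original copper-death screen	FDX1	LIAS	LIPT1	DLD	DLAT	PDHA1	PDHB
FPI_positive_example	synthetic example ferroptosis driver set for demonstrations; not a curated signature	ACSL4	ALOX15	TFRC	NCOA4	SAT1	GLS2	HMOX1
FPI_negative_example	synthetic example ferroptosis suppressor set for demonstrations; not a curated signature	GPX4	SLC7A11	NFE2L2	FTH1	HSPB1	AIFM2
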