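gene_a	gene_b	desc_a	desc_b	module	notes
ENSG00000160185;UBASH3A	ENSG00000153283;CD96	ubiquitin associated and SH3 domain containing A	CD96 molecule	TM0023	&,‡,†,*
ENSG00000183918;SH2D1A	ENSG00000160185;UBASH3A	SH2 domain containing 1A	ubiquitin associated and SH3 domain containing A	TM0023	%,‡,†,*
ENSG00000162739;SLAMF6	ENSG00000160185;UBASH3A	SLAM family member 6	ubiquitin associated and SH3 domain containing A	TM0023	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000101082;SLA2	ubiquitin associated and SH3 domain containing A	Src like adaptor 2	TM0023	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000116824;CD2	ubiquitin associated and SH3 domain containing A	CD2 molecule	TM0021	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000089012;SIRPG	ubiquitin associated and SH3 domain containing A	signal regulatory protein gamma	TM0021	&,‡,†,*
ENSG00000277734;TRAC	ENSG00000160185;UBASH3A	T cell receptor alpha constant	ubiquitin associated and SH3 domain containing A	TM0021	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000137078;SIT1	ubiquitin associated and SH3 domain containing A	signaling threshold regulating transmembrane adaptor 1	TM0021	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000147168;IL2RG	ubiquitin associated and SH3 domain containing A	interleukin 2 receptor subunit gamma	TM0021	&,‡,†,*
ENSG00000167286;CD3D	ENSG00000160185;UBASH3A	CD3d molecule	ubiquitin associated and SH3 domain containing A	TM0021	&,‡,†,*
ENSG00000182866;LCK	ENSG00000160185;UBASH3A	LCK proto-oncogene, Src family tyrosine kinase	ubiquitin associated and SH3 domain containing A	TM0021	&,‡,†,*
ENSG00000198851;CD3E	ENSG00000160185;UBASH3A	CD3e molecule	ubiquitin associated and SH3 domain containing A	TM0021	&,‡,†,*
ENSG00000163564;PYHIN1	ENSG00000160185;UBASH3A	pyrin and HIN domain family member 1	ubiquitin associated and SH3 domain containing A	NA	&,‡,†,*
ENSG00000231890;DARS-AS1	ENSG00000227191;TCRGC2	DARS antisense RNA 1	T Cell Receptor Gamma Constant 2	NA	&,‡,†,*
ENSG00000281881;SPRY4-IT1	ENSG00000109920;FNBP4	SPRY4 intronic transcript 1	formin binding protein 4	NA	&,‡,†,*
ENSG00000161405;IKZF3	ENSG00000160185;UBASH3A	IKAROS family zinc finger 3	ubiquitin associated and SH3 domain containing A	NA	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000143851;PTPN7	ubiquitin associated and SH3 domain containing A	protein tyrosine phosphatase, non-receptor type 7	NA	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000104814;MAP4K1	ubiquitin associated and SH3 domain containing A	mitogen-activated protein kinase kinase kinase kinase 1	NA	&,‡,†,*
ENSG00000160185;UBASH3A	ENSG00000005844;ITGAL	ubiquitin associated and SH3 domain containing A	integrin subunit alpha L	NA	&,‡,†,*
ENSG00000263970;RP11-789C17.5	ENSG00000054148;PHPT1	Antisense RNA	phosphohistidine phosphatase 1	NA	&,‡,†,*
ENSG00000272505;RP11-981G7.6	ENSG00000253641;LINCR-0001	lincRNA	uncharacterized LINCR-0001	NA	&,‡,†,*
ENSG00000234290;AC116366.6	ENSG00000197536;C5orf56	Antisense RNA	chromosome 5 open reading frame 56	NA	&,‡,†,*
ENSG00000237721;AF064858.3	ENSG00000235888;AF064858.1	lincRNA	lincRNA	NA	&,‡,†,*
ENSG00000231233;CCDC147-AS1	ENSG00000184277;TM2D3	CCDC147 antisense RNA 1	TM2 domain containing 3	NA	&,‡,†,*
ENSG00000251320;AC011352.3	ENSG00000248362;AC011352.1	lncRNA	lncRNA	NA	&,‡,†,*
ENSG00000218227;RPL19P9	ENSG00000204677;FAM153C	Ribosomal Protein L19 Pseudogene 9	family with sequence similarity 153 member C	NA	&,‡,†,*
ENSG00000237471;AC073115.2	ENSG00000229628;AC073115.7	lincRNA	lincRNA	NA	&,‡,†,*
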