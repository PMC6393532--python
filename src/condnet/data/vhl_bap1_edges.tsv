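gene_a	gene_b	desc_a	desc_b	module	notes
ENSG00000183918;SH2D1A	ENSG00000181847;TIGIT	SH2 domain containing 1A	T cell immunoreceptor with Ig and ITIM domains	TM0006	&,‡,†,*
ENSG00000181847;TIGIT	ENSG00000162739;SLAMF6	T cell immunoreceptor with Ig and ITIM domains	SLAM family member 6	TM0006	&,‡,†,*
ENSG00000181847;TIGIT	ENSG00000153283;CD96	T cell immunoreceptor with Ig and ITIM domains	CD96 molecule	TM0006	&,‡,†,*
ENSG00000181847;TIGIT	ENSG00000101082;SLA2	T cell immunoreceptor with Ig and ITIM domains	Src like adaptor 2	TM0006	&,‡,†,*
ENSG00000198846;TOX	ENSG00000049249;TNFRSF9	thymocyte selection associated high mobility group box	TNF receptor superfamily member 9	NA	&,‡,†,*
ENSG00000153563;CD8A	ENSG00000049249;TNFRSF9	CD8a molecule	TNF receptor superfamily member 9	NA	&,‡,†,*
ENSG00000163508;EOMES	ENSG00000049249;TNFRSF9	eomesodermin	TNF receptor superfamily member 9	NA	&,‡,†,*
ENSG00000181847;TIGIT	ENSG00000089012;SIRPG	T cell immunoreceptor with Ig and ITIM domains	signal regulatory protein gamma	NA	&,‡,†,*
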