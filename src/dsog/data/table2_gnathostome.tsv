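#group_id	description	rep_gene	acc_a	name_a	acc_b	name_b	other_genes
GGG01	Butyrophilin subfamily 1 member A1	ENSG00000124557	PF00622	SPRY	PF08205	C2-set_2
GGG01	Butyrophilin subfamily 1 member A1	ENSG00000124557	PF00047	ig	PF00622	SPRY	ENSG00000112763,ENSG00000124508,ENSG00000026950,ENSG00000111801,ENSG00000164010
GGG01	Butyrophilin subfamily 1 member A1	ENSG00000124557	PF00622	SPRY	PF13927	Ig_3	ENSG00000113303,ENSG00000168903,ENSG00000165810,ENSG00000112763,ENSG00000124508,ENSG00000026950,ENSG00000111801,ENSG00000164010
GGG02	Myosin X	ENSG00000145555	PF00063	Myosin_head	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF00169	PH	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF00373	FERM_M	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF00612	IQ	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF00784	MyTH4	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF00788	RA	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF14593	PH_3	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF15409	PH_8	PF16735	MYO10_CC
GGG02	Myosin X	ENSG00000145555	PF15413	PH_11	PF16735	MYO10_CC
GGG03	OCRL, inositol polyphosphate-5-phosphatase	ENSG00000122126	PF00620	RhoGAP	PF16726	OCRL_clath_bd
GGG03	OCRL, inositol polyphosphate-5-phosphatase	ENSG00000122126	PF03372	Exo_endo_phos	PF16726	OCRL_clath_bd
GGG04	Sushi repeat containing protein, X-linked 2	ENSG00000102359	PF00084	Sushi	PF13778	DUF4174	ENSG00000101955
GGG04	Sushi repeat containing protein, X-linked 2	ENSG00000102359	PF02494	HYR	PF13778	DUF4174	ENSG00000101955
GGG05	UEV and lactate/malate dehyrogenase domains	ENSG00000151116	PF00056	Ldh_1_N	PF05743	UEV
GGG05	UEV and lactate/malate dehyrogenase domains	ENSG00000151116	PF02866	Ldh_1_C	PF05743	UEV
GGG06	Zinc finger protein 536	ENSG00000198597	PF00096	zf-C2H2	PF16606	zf-C2H2_assoc
GGG06	Zinc finger protein 536	ENSG00000198597	PF05605	zf-Di19	PF16606	zf-C2H2_assoc
GGG06	Zinc finger protein 536	ENSG00000198597	PF13465	zf-H2C2_2	PF16606	zf-C2H2_assoc
GGG06	Zinc finger protein 536	ENSG00000198597	PF13894	zf-C2H2_4	PF16606	zf-C2H2_assoc
GGG06	Zinc finger protein 536	ENSG00000198597	PF13909	zf-H2C2_5	PF16606	zf-C2H2_assoc
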