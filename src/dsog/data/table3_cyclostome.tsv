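#group_id	description	rep_gene	acc_a	name_a	acc_b	name_b	other_genes
CGG01	ARL8B_homolog	g6788	PF00025	Arf	PF00583	Acetyltransf_1
CGG01	ARL8B_homolog	g6788	PF00503	G-alpha	PF00583	Acetyltransf_1
CGG01	ARL8B_homolog	g6788	PF00583	Acetyltransf_1	PF01926	MMR_HSR1
CGG01	ARL8B_homolog	g6788	PF00583	Acetyltransf_1	PF04670	Gtr1_RagA
CGG01	ARL8B_homolog	g6788	PF00583	Acetyltransf_1	PF08477	Roc
CGG01	ARL8B_homolog	g6788	PF00583	Acetyltransf_1	PF09439	SRPRB
CGG02	CCDC94_homolog	g2903	PF04502	DUF572	PF14936	p53-inducible11
CGG03	DOCK1_homolog	g2681	PF08506	Cse1	PF14429	DOCK-C2
CGG04	HYI_homolog	g1738	PF01261	AP_endonuc_2	PF01907	Ribosomal_L37e
CGG05	KCNS3_homolog	g4934	PF02724	CDC45	PF10446	DUF2457
CGG06	MCAM_homolog	g10860	PF00047	ig	PF12301	CD99L2
CGG06	MCAM_homolog	g10860	PF07679	I-set	PF12301	CD99L2
CGG06	MCAM_homolog	g10860	PF07686	V-set	PF12301	CD99L2
CGG06	MCAM_homolog	g10860	PF08205	C2-set_2	PF12301	CD99L2
CGG06	MCAM_homolog	g10860	PF12301	CD99L2	PF13895	Ig_2
CGG06	MCAM_homolog	g10860	PF12301	CD99L2	PF13927	Ig_3
CGG07	NWD2_homolog	g4096	PF07569	Hira	PF13271	DUF4062
CGG08	PARG_homolog	g7740	PF05028	PARG_cat	PF05716	AKAP_110
CGG09	PPAT_homolog	g4078	PF00153	Mito_carr	PF00156	Pribosyltran
CGG10	PROX1_homolog	g2781	PF00769	ERM	PF05044	HPD
CGG11	SETMAR_homolog	g18133	PF13565	HTH_32	PF16087	DUF4817
CGG12	SLIT2_homolog	g14957	PF11921	DUF3439	PF12799	LRR_4	g24021
CGG12	SLIT2_homolog	g14957	PF11921	DUF3439	PF13306	LRR_5
CGG12	SLIT2_homolog	g14957	PF11921	DUF3439	PF13855	LRR_8	g24021
CGG13	TIGD1_homolog	g15228	PF01722	BolA	PF04218	CENP-B_N
CGG13	TIGD1_homolog	g15228	PF04218	CENP-B_N	PF13465	zf-H2C2_2	g17584
CGG13	TIGD1_homolog	g15228	PF04218	CENP-B_N	PF13894	zf-C2H2_4	g5746,g17584
CGG14	TIGD2_homolog	g5746	PF13518	HTH_28	PF13894	zf-C2H2_4
CGG15	TOM1L2_homolog	g7950	PF00790	VHS	PF15002	ERK-JNK_inhib
CGG15	TOM1L2_homolog	g7950	PF03127	GAT	PF15002	ERK-JNK_inhib
CGG16	TRIM14_homolog	g1602	PF00020	TNFR_c6	PF00622	SPRY	g14212
CGG16	TRIM14_homolog	g1602	PF00020	TNFR_c6	PF13765	PRY	g14212,g14213
CGG17	zinc finger protein 3-like isoform X1	LOC116946555	PF13465	zf-H2C2_2	PF13518	HTH_28
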