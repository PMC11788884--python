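#group_id	description	rep_gene	acc_a	name_a	acc_b	name_b	other_genes
VGG01	Angiotensin I converting enzyme 2	ENSG00000130234	PF01401	Peptidase_M2	PF16959	Collectrin
VGG02	Attractin like 1	ENSG00000107518	PF00059	Lectin_C	PF01437	PSI	ENSG00000088812
VGG02	Attractin like 1	ENSG00000107518	PF00059	Lectin_C	PF17205	PSI_integrin
VGG03	Carboxypeptidase X, M14 family member 1	ENSG00000088882	PF00246	Peptidase_M14	PF00754	F5_F8_type_C	ENSG00000121898,ENSG00000106624
VGG03	Carboxypeptidase X, M14 family member 1	ENSG00000088882	PF00754	F5_F8_type_C	PF13620	CarboxypepD_reg	ENSG00000121898,ENSG00000106624
VGG03	Carboxypeptidase X, M14 family member 1	ENSG00000088882	PF00754	F5_F8_type_C	PF13715	CarbopepD_reg_2	ENSG00000106624
VGG04	Cartilage acidic protein 1	ENSG00000095713	PF01839	FG-GAP	PF07645	EGF_CA
VGG04	Cartilage acidic protein 1	ENSG00000095713	PF07593	UnbV_ASPIC	PF07645	EGF_CA
VGG04	Cartilage acidic protein 1	ENSG00000095713	PF07645	EGF_CA	PF13517	VCBS
VGG05	Coagulation factor II, thrombin	ENSG00000180210	PF00051	Kringle	PF00594	Gla
VGG06	Discs large MAGUK scaffold protein 1	ENSG00000075711	PF09058	L27_1	PF10608	MAGUK_N_PEST	ENSG00000132535,ENSG00000150672
VGG07	Elastin microfibril interfacer 3	ENSG00000183798	PF04582	Reo_sigmaC	PF07546	EMI	ENSG00000132205
VGG08	F-box protein 9	ENSG00000112146	PF00646	F-box	PF04212	MIT
VGG08	F-box protein 9	ENSG00000112146	PF04212	MIT	PF12937	F-box-like
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF00050	Kazal_1	PF13365	Trypsin_2	ENSG00000166033
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF00089	Trypsin	PF00219	IGFBP	ENSG00000166033,ENSG00000169495
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF00219	IGFBP	PF00595	PDZ	ENSG00000166033,ENSG00000169495
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF00219	IGFBP	PF10459	Peptidase_S46	ENSG00000166033,ENSG00000169495
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF00219	IGFBP	PF13180	PDZ_2	ENSG00000166033,ENSG00000169495
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF00219	IGFBP	PF13365	Trypsin_2	ENSG00000166033,ENSG00000169495
VGG09	HtrA serine peptidase 3	ENSG00000170801	PF07648	Kazal_2	PF13365	Trypsin_2	ENSG00000166033,ENSG00000169495
VGG10	Hyaluronan and proteoglycan link protein 2	ENSG00000132702	PF00047	ig	PF00193	Xlink	ENSG00000140511,ENSG00000132692,ENSG00000187664
VGG10	Hyaluronan and proteoglycan link protein 2	ENSG00000132702	PF00193	Xlink	PF07686	V-set	ENSG00000157766,ENSG00000140511,ENSG00000132692,ENSG00000130287,ENSG00000187664,ENSG00000038427,ENSG00000145681
VGG10	Hyaluronan and proteoglycan link protein 2	ENSG00000132702	PF00193	Xlink	PF13927	Ig_3	ENSG00000140511,ENSG00000187664,ENSG00000145681
VGG11	Integrin subunit beta 4	ENSG00000132470	PF03160	Calx-beta	PF07965	Integrin_B_tail
VGG11	Integrin subunit beta 4	ENSG00000132470	PF07965	Integrin_B_tail	PF16656	Pur_ac_phosph_N
VGG12	Mannose receptor C-type 1	ENSG00000260314	PF00040	fn2	PF00652	Ricin_B_lectin
VGG12	Mannose receptor C-type 1	ENSG00000260314	PF00652	Ricin_B_lectin	PF05473	UL45
VGG13	MARVEL domain containing 2	ENSG00000152939	PF01284	MARVEL	PF07303	Occludin_ELL	ENSG00000274671,ENSG00000273814,ENSG00000197822
VGG14	Matrilin 4	ENSG00000124159	PF00008	EGF	PF10393	Matrilin_ccoil	ENSG00000132561,ENSG00000132031
VGG14	Matrilin 4	ENSG00000124159	PF00092	VWA	PF10393	Matrilin_ccoil	ENSG00000162510,ENSG00000132561,ENSG00000132031
VGG14	Matrilin 4	ENSG00000124159	PF07645	EGF_CA	PF10393	Matrilin_ccoil	ENSG00000162510,ENSG00000132561,ENSG00000132031
VGG14	Matrilin 4	ENSG00000124159	PF10393	Matrilin_ccoil	PF12662	cEGF	ENSG00000162510,ENSG00000132561,ENSG00000132031
VGG14	Matrilin 4	ENSG00000124159	PF10393	Matrilin_ccoil	PF13519	VWA_2	ENSG00000162510,ENSG00000132561,ENSG00000132031
VGG14	Matrilin 4	ENSG00000124159	PF10393	Matrilin_ccoil	PF14670	FXa_inhibition	ENSG00000162510,ENSG00000132561,ENSG00000132031
VGG15	Matrix metallopeptidase 23B	ENSG00000189409	PF00413	Peptidase_M10	PF13895	Ig_2
VGG15	Matrix metallopeptidase 23B	ENSG00000189409	PF00413	Peptidase_M10	PF13927	Ig_3
VGG16	Matrix metallopeptidase 24	ENSG00000125966	PF00045	Hemopexin	PF11857	DUF3377	ENSG00000102996,ENSG00000157227,ENSG00000156103
VGG16	Matrix metallopeptidase 24	ENSG00000125966	PF00413	Peptidase_M10	PF11857	DUF3377	ENSG00000102996,ENSG00000157227,ENSG00000156103
VGG16	Matrix metallopeptidase 24	ENSG00000125966	PF01400	Astacin	PF11857	DUF3377	ENSG00000157227,ENSG00000156103
VGG16	Matrix metallopeptidase 24	ENSG00000125966	PF01471	PG_binding_1	PF11857	DUF3377	ENSG00000102996,ENSG00000157227,ENSG00000156103
VGG17	Multimerin 1	ENSG00000138722	PF00386	C1q	PF07546	EMI	ENSG00000132205,ENSG00000138080,ENSG00000173269
VGG18	Platelet derived growth factor C	ENSG00000145431	PF00341	PDGF	PF00431	CUB	ENSG00000170962
VGG19	Protein C, inactivator of coagulation factors Va and VIIIa	ENSG00000115718	PF00089	Trypsin	PF00594	Gla	ENSG00000101981,ENSG00000057593,ENSG00000126231,ENSG00000126218,ENSG00000180210
VGG19	Protein C, inactivator of coagulation factors Va and VIIIa	ENSG00000115718	PF00594	Gla	PF09342	DUF1986	ENSG00000057593,ENSG00000101981
VGG19	Protein C, inactivator of coagulation factors Va and VIIIa	ENSG00000115718	PF00594	Gla	PF13365	Trypsin_2	ENSG00000101981,ENSG00000126218
VGG20	Protein tyrosine phosphatase, receptor type Z1	ENSG00000106278	PF00041	fn3	PF00194	Carb_anhydrase	ENSG00000144724
VGG20	Protein tyrosine phosphatase, receptor type Z1	ENSG00000106278	PF00102	Y_phosphatase	PF00194	Carb_anhydrase	ENSG00000144724
VGG20	Protein tyrosine phosphatase, receptor type Z1	ENSG00000106278	PF00194	Carb_anhydrase	PF00782	DSPc	ENSG00000144724
VGG21	Retinoid X receptor gamma	ENSG00000143171	PF00104	Hormone_recep	PF11825	Nuc_recep-AF1	ENSG00000235712,ENSG00000228333,ENSG00000227322,ENSG00000231321,ENSG00000206289,ENSG00000186350,ENSG00000204231
VGG21	Retinoid X receptor gamma	ENSG00000143171	PF00105	zf-C4	PF11825	Nuc_recep-AF1	ENSG00000235712,ENSG00000228333,ENSG00000227322,ENSG00000231321,ENSG00000206289,ENSG00000186350,ENSG00000204231
VGG22	Retinol binding protein 3	ENSG00000265203	PF03572	Peptidase_S41	PF11918	Peptidase_S41_N
VGG23	SATB homeobox 2	ENSG00000119042	PF02376	CUT	PF16534	ULD	ENSG00000182568
VGG24	SEL1L ERAD E3 ligase adaptor subunit	ENSG00000071537	PF00040	fn2	PF08238	Sel1
VGG25	Semaphorin 4G	ENSG00000095539	PF01437	PSI	PF13895	Ig_2	ENSG00000138623,ENSG00000168758
VGG26	Sushi domain containing 2	ENSG00000099994	PF01033	Somatomedin_B	PF03782	AMOP
VGG27	Synaptotagmin 2	ENSG00000143858	PF00168	C2	PF15807	MAP17
VGG28	TNFRSF1A associated via death domain	ENSG00000102871	PF00531	Death	PF09034	TRADD_N
VGG29	Transient receptor potential cation channel subfamily M member 7	ENSG00000092439	PF00520	Ion_trans	PF02816	Alpha_kinase	ENSG00000119121
VGG29	Transient receptor potential cation channel subfamily M member 7	ENSG00000092439	PF02816	Alpha_kinase	PF16519	TRPM_tetra	ENSG00000119121
VGG30	Tyrosine kinase non receptor 2	ENSG00000061938	PF07714	Pkinase_Tyr	PF11555	Inhibitor_Mig-6
VGG30	Tyrosine kinase non receptor 2	ENSG00000061938	PF11555	Inhibitor_Mig-6	PF14555	UBA_4
VGG31	Zona pellucida glycoprotein 4	ENSG00000116996	PF00088	Trefoil	PF00100	Zona_pellucida
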