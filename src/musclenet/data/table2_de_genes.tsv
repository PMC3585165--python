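probe_id	gene_title	gene_symbol	p_value	p_censored	fold_change
206633_at	cholinergic receptor, nicotinic, alpha 1 (muscle)	CHRNA1	0.0001	1	18.96
203725_at	growth arrest and DNA-damage-inducible, alpha	GADD45A	0.0001	1	9.47
208623_s_at	ezrin	EZR	0.0001	1	3.83
201012_at	annexin A1	ANXA1	0.0001	1	4.16
206559_x_at	eukaryotic translation elongation factor 1 alpha 1	EEF1A1	0.0001	1	4.19
201037_at	phosphofructokinase, platelet	PFKP	0.0001	1	2.59
202237_at	nicotinamide N-methyltransferase	NNMT	0.0001	1	8.11
37996_s_at	dystrophia myotonica-protein kinase	DMPK	0.0001	1	3.46
204892_x_at	eukaryotic translation elongation factor 1 alpha 1	EEF1A1	0.0001	1	4.35
217755_at	hematological and neurological expressed 1	HN1	0.0001	1	2.25
209288_s_at	CDC42 effector protein (Rho GTPase binding) 3	CDC42EP3	0.0001	1	6.83
204802_at	Ras-related associated with diabetes	RRAD	0.0001	1	3.71
204225_at	histone deacetylase 4	HDAC4	0.0001	1	3.25
207024_at	cholinergic receptor, nicotinic, delta	CHRND	0.0001	1	2.19
211340_s_at	melanoma cell adhesion molecule	MCAM	0.0001	1	2.09
201289_at	cysteine-rich, angiogenic inducer, 61	CYR61	0.0001	1	3.98
203571_s_at	chromosome 10 open reading frame 116	C10orf116	0.0001	1	3.84
209014_at	melanoma antigen family D, 1	MAGED1	0.0001	1	2.50
202769_at	cyclin G2	CCNG2	0.0001	1	2.97
202284_s_at	cyclin-dependent kinase inhibitor 1A (p21, Cip1)	CDKN1A	0.0001	1	5.62
202310_s_at	collagen, type I, alpha 1	COL1A1	0.0001	1	4.05
218718_at	platelet derived growth factor C	PDGFC	0.0001	1	2.96
202403_s_at	collagen, type I, alpha 2	COL1A2	0.0001	1	2.90
205145_s_at	myosin, light chain 5, regulatory	MYL5	0.0001	1	4.17
208682_s_at	melanoma antigen family D, 2	MAGED2	0.0001	1	2.42
220359_s_at	cAMP-regulated phosphoprotein, 21 kDa	ARPP21	0.0001	1	3.52
222162_s_at	ADAM metallopeptidase with thrombospondin type 1 motif, 1	ADAMTS1	0.0001	1	3.46
207282_s_at	myogenin (myogenic factor 4)	MYOG	0.0001	1	2.27
200782_at	annexin A5	ANXA5	0.0001	1	2.04
205132_at	actin, alpha, cardiac muscle 1	ACTC1	0.0001	1	4.72
201666_at	TIMP metallopeptidase inhibitor 1	TIMP1	0.00011	0	2.11
203186_s_at	S100 calcium binding protein A4	S100A4	0.00011	0	2.05
204257_at	fatty acid desaturase 3	FADS3	0.00011	0	2.03
209785_s_at	phospholipase A2, group IVC	PLA2G4C	0.00011	0	2.13
202157_s_at	CUGBP, Elav-like family member 2	CELF2	0.00012	0	2.05
203579_s_at	solute carrier family 7, member 6	SLC7A6	0.00014	0	3.33
206703_at	cholinergic receptor, nicotinic, beta 1 (muscle)	CHRNB1	0.00014	0	2.65
200665_s_at	secreted protein, acidic, cysteine-rich (osteonectin)	SPARC	0.00014	0	2.59
201368_at	zinc finger protein 36, C3H type-like 2	ZFP36L2	0.00017	0	2.58
202724_s_at	forkhead box O1	FOXO1	0.00018	0	2.14
217728_at	S100 calcium binding protein A6	S100A6	0.00018	0	2.50
202854_at	hypoxanthine phosphoribosyltransferase 1	HPRT1	0.00020	0	2.34
201300_s_at	prion protein	PRNP	0.00021	0	2.82
34471_at	myosin, heavy chain 8, skeletal muscle, perinatal	MYH8	0.00033	0	5.52
203232_s_at	ataxin 1	ATXN1	0.00033	0	2.35
202133_at	WW domain containing transcription regulator 1	WWTR1	0.00033	0	2.07
203156_at	A kinase (PRKA) anchor protein 11	AKAP11	0.00033	0	2.06
201141_at	glycoprotein (transmembrane) nmb	GPNMB	0.00034	0	2.16
208683_at	calpain 2, (m/II) large subunit	CAPN2	0.00041	0	2.16
205940_at	myosin, heavy chain 3, skeletal muscle, embryonic	MYH3	0.00042	0	4.09
212271_at	mitogen-activated protein kinase 1	MAPK1	0.00042	0	2.14
204039_at	CCAAT/enhancer binding protein (C/EBP), alpha	CEBPA	0.00047	0	2.40
200603_at	protein kinase, cAMP-dependent, regulatory, type I, alpha	PRKAR1A	0.00047	0	2.02
219825_at	cytochrome P450, family 26, subfamily B, polypeptide 1	CYP26B1	0.00058	0	2.73
211962_s_at	zinc finger protein 36, C3H type-like 1	ZFP36L1	0.00058	0	2.49
211161_s_at	collagen, type III, alpha 1	COL3A1	0.00059	0	3.07
201417_at	SRY (sex determining region Y)-box 4	SOX4	0.00060	0	2.36
209118_s_at	tubulin, alpha 1a	TUBA1A	0.00073	0	2.11
201530_x_at	eukaryotic translation initiation factor 4A1	EIF4A1	0.00076	0	2.22
206717_at	myosin, heavy chain 8, skeletal muscle, perinatal	MYH8	0.00080	0	5.91
201761_at	methylenetetrahydofolate dehydrogenase 2	MTHFD2	0.00099	0	2.74
202995_s_at	fibulin 1	FBLN1	0.00099	0	2.49
201744_s_at	lumican	LUM	0.00100	0	2.31
202598_at	S100 calcium binding protein A13	S100A13	0.00102	0	2.18
200059_s_at	ras homolog gene family, member A	RHOA	0.00102	0	2.09
206306_at	ryanodine receptor 3	RYR3	0.00108	0	3.46
206059_at	zinc finger protein 91	ZNF91	0.00139	0	2.14
211985_s_at	calmodulin 1 (phosphorylase kinase, delta)	CALM1	0.00162	0	2.51
212670_at	elastin	ELN	0.00170	0	2.50
200696_s_at	gelsolin	GSN	0.00175	0	2.05
212099_at	ras homolog gene family, member B	RHOB	0.00287	0	3.05
201329_s_at	v-ets erythroblastosis virus E26 oncogene homolog 2	ETS2	0.00334	0	2.74
200866_s_at	prosaposin	PSAP	0.00376	0	2.27
201426_s_at	vimentin	VIM	0.00430	0	2.62
204719_at	ATP-binding cassette, sub-family A (ABC1), member 8	ABCA8	0.00447	0	2.08
206372_at	myogenic factor 6 (herculin)	MYF6	0.00461	0	2.13
202838_at	fucosidase, alpha-L- 1, tissue	FUCA1	0.00493	0	2.20
207992_s_at	adenosine monophosphate deaminase 3	AMPD3	0.00529	0	2.06
201946_s_at	chaperonin containing TCP1, subunit 2 (beta)	CCT2	0.00578	0	2.32
208607_s_at	serum amyloid A1/serum amyloid A2	SAA1/SAA2	0.01840	0	2.10
205589_at	myosin, light chain 3, alkali; ventricular, skeletal, slow	MYL3	0.00017	0	-2.66
203766_s_at	leiomodin 1 (smooth muscle)	LMOD1	0.00062	0	-2.28
205738_s_at	fatty acid binding protein 3, muscle and heart	FABP3	0.00151	0	-2.99
202428_x_at	diazepam binding inhibitor	DBI	0.00176	0	-2.27
205736_at	phosphoglycerate mutase 2 (muscle)	PGAM2	0.00185	0	-3.14
218818_at	four and a half LIM domains 3	FHL3	0.00384	0	-2.39
205330_at	meningioma (disrupted in balanced translocation) 1	MN1	0.00397	0	-2.55
219983_at	HRAS-like suppressor	HRASLS	0.00397	0	-2.11
205478_at	protein phosphatase 1, regulatory (inhibitor) subunit 1A	PPP1R1A	0.00421	0	-2.45
204483_at	enolase 3 (beta, muscle)	ENO3	0.00924	0	-2.17
216733_s_at	glycine amidinotransferase	GATM	0.00981	0	-2.01
206891_at	actinin, alpha 3	ACTN3	0.01094	0	-4.82
206844_at	fructose-1,6-bisphosphatase 2	FBP2	0.01511	0	-2.97
203824_at	tetraspanin 8	TSPAN8	0.01882	0	-2.10
204783_at	myeloid leukemia factor 1	MLF1	0.02132	0	-2.53
208691_at	transferrin receptor (p90, CD71)	TFRC	0.02744	0	-2.28
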