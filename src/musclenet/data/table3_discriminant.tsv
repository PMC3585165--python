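rank	gene_symbol	description	mitochondrial	muscle_specific	in_de_list
1	ACTN3	actinin, alpha 3	1	1	1
2	PGAM2	phosphoglycerate mutase 2	0	1	1
3	MYL3	myosin, light chain 3, alkali; ventricular, skeletal, slow	0	1	1
4	MLF1	myeloid leukemia factor 1	0	0	1
5	FBP2	fructose-1,6-bisphosphatase 2	1	1	1
6	DBI	diazepam binding inhibitor	0	0	1
7	ENO3	enolase 3	0	1	1
8	PPP1R1A	protein phosphatase 1, regulatory (inhibitor) subunit 1A	0	0	1
9	FABP3	fatty acid binding protein 3	0	1	1
10	COX6A2	cytochrome c oxidase subunit VIa polypeptide 2	1	0	0
11	MN1	meningioma	0	0	1
12	FHL3	four and a half LIM domains 3	0	1	1
13	FEZ2	fasciculation and elongation protein zeta 2	0	0	0
14	TFRC	transferrin receptor (p90, CD71)	0	1	1
15	LMOD1	leiomodin 1	0	1	1
16	SEPW1	selenoprotein W	0	0	0
17	TSPAN8	tetraspanin 8	0	0	1
18	HRASLS	HRAS-like suppressor	1	0	1
19	COX8A	cytochrome c oxidase subunit VIIIA	1	0	0
20	GMPR	guanosine monophosphate reductase	0	0	0
21	LMCD1	LIM and cysteine-rich domains 1	0	0	0
22	NDUFA3	NADH dehydrogenase (ubiquinone) 1 alpha subcomplex, 3, 9 kDa	1	0	0
23	COX6B1	cytochrome c oxidase sub VIb polypeptide 1	1	0	0
24	MYH2	myosin, heavy chain 2, skeletal muscle, adult	0	1	0
25	ATP5J	ATP synthase, H+ transporting, mitochondrial Fo complex, subunit F6	0	0	0
26	NDUFB3	NADH dehydrogenase 1 beta subcomplex, 3	1	0	0
27	RPL3L	ribosomal protein L3-like	0	0	0
28	C14orf2	chromosome 14 open reading frame 2	1	0	0
29	NDUFB4	NADH dehydrogenase 1 beta subcomplex, 4,	1	0	0
30	ART3	ADP-ribosyltransferase 3	0	1	0
31	MYOM2	myomesin (M-protein) 2, 165 kDa	0	1	0
32	COX6C	cytochrome c oxidase subunit VIc	1	0	0
33	MKNK2	MAP kinase interacting serine/threonine kinase 2	1	0	0
34	COX7C	cytochrome c oxidase subunit VIIc	1	0	0
35	FKBP3	FK506 binding protein 3, 25 kDa	0	0	0
36	G0S2	G0/G1switch 2	0	0	0
37	COX7A1	cytochrome c oxidase subunit VIIa polypeptide 1	1	0	0
38	COX5B	cytochrome c oxidase subunit Vb	1	0	0
39	MEFV	Mediterranean fever	0	1	0
40	NDUFAB1	NADH dehydrogenase 1, alpha/beta subcomplex	1	0	0
41	MRPL33	mitochondrial ribosomal protein L33	1	0	0
42	NDUFA6	NADH dehydrogenase 1 alpha subcomplex 6	1	0	0
43	NDUFA4	NADH dehydrogenase1 alpha subcomplex, 4	1	0	0
44	ATP5G1	ATP synthase, H+ transporting, mitochondrial Fo complex, subunit C1 (subunit 9)	0	0	0
45	HOXA10	homeobox A10	1	0	0
46	MYOT	myotilin	0	1	0
47	PPP1R3C	protein phosphatase 1, regulatory (inhibitor) subunit 3C	0	0	0
48	ATPIF1	ATPase inhibitory factor 1	0	0	0
49	MGST3	microsomal glutathione S-transferase 3	1	0	0
50	VEGFA	vascular endothelial growth factor A	0	0	0
51	MAGED1	melanoma antigen family D, 1	0	1	1
52	HPRT1	hypoxanthine phosphoribosyltransferase 1	1	0	1
53			0	0	0
54	ABCA8	ATP-binding cassette, sub-family A (ABC1), member 8	0	0	1
55	SOX4	SRY (sex determining region Y)-box 4	1	0	1
56	ATXN1	ataxin 1	1	0	1
57	FBLN1	fibulin 1	1	0	1
58	PSAP	prosaposin	0	0	1
59	NDRG2	NDRG family member 2	0	0	0
60	COL1A2	collagen, type I, alpha 2	0	0	1
61	SPARC	secreted protein, acidic, cysteine-rich (osteonectin)	0	0	1
62	CHRNB1	cholinergic receptor, nicotinic, beta 1 (muscle)	0	1	1
63	ZFP36L1	zinc finger protein 36, C3H type-like 1	1	0	1
64	CCNG2	cyclin G2	1	0	1
65	MTHFD2	methylenetetrahydrofolate dehydrogenase	0	0	1
66	ZFP36L2	zinc finger protein 36, C3H type-like 2	1	0	1
67	CALM1	calmodulin 1 (phosphorylase kinase, delta)	1	0	1
68	CYP26B1	cytochrome P450, family 26, subfamily B, polypeptide 1	0	0	1
69	CCT2	chaperonin containing TCP1, subunit 2 (beta)	0	0	1
70	RYR3	ryanodine receptor 3	0	0	1
71	COL3A1	collagen, type III, alpha 1	1	0	1
72	NRAP	nebulin-related anchoring protein	0	1	0
73	PDGFC	platelet derived growth factor C	0	0	1
74	ETS2	v-ets erythroblastosis virus E26 oncogene homolog 2	0	0	1
75	VIM	vimentin	0	0	1
76	PRNP	prion protein	0	0	1
77	DMPK	dystrophia myotonica-protein kinase	0	1	1
78	ADAMTS1	ADAM metallopeptidase with thrombospondin type 1 motif, 1	0	0	1
79	SLC7A6	solute carrier family 7 (cationic amino acid transporter, y+ system), member 6	1	0	1
80	RHOB	ras homolog gene family, member B	1	0	1
81	ARPP21	cAMP-regulated phosphoprotein, 21 kDa	0	0	1
82	COL1A1	collagen, type I, alpha 1	0	0	1
83	EZR	ezrin	0	1	1
84	HDAC4	histone deacetylase 4	0	1	1
85	CYR61	cysteine-rich, angiogenic inducer, 61	0	0	1
86	C10orf116	chromosome 10 open reading frame 116	1	0	1
87	ANXA1	annexin A1	0	1	1
88	MYL5	myosin, light chain 5, regulatory	0	1	1
89	EEF1A1	eukaryotic translation elongation factor 1 alpha 1	0	1	1
90	RRAD	Ras-related associated with diabetes	0	0	1
91	EEF1A1	eukaryotic translation elongation factor 1 alpha 1	0	0	1
92	MYH3	myosin, heavy chain 3, skeletal muscle, embryonic	0	1	1
93	CDKN1A	cyclin-dependent kinase inhibitor 1A (p21, Cip1)	0	0	1
94	ACTC1	actin, alpha, cardiac muscle 1	0	1	1
95	MYH8	myosin, heavy chain 8, skeletal muscle, perinatal	0	1	1
96	MYH8	myosin, heavy chain 8, skeletal muscle, perinatal	0	1	1
97	CDC42EP3	CDC42 effector protein (Rho GTPase binding) 3	0	1	1
98	NNMT	nicotinamide N-methyltransferase	0	0	1
99	GADD45A	growth arrest and DNA-damage-inducible, alpha	0	0	1
100	CHRNA1	cholinergic receptor, nicotinic, alpha 1 (muscle)	0	1	1
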