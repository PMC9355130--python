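id	age_at_dx	status	year	morphology	stage	family_history	gene	surgery
1	32	I	2021	IDC G3, TNBC; + DCIS focal lesions, Ki67-80%	IB	Mother´s side: BC, 38, 46, 47; OC, 56, 57	BRCA1	no
2	34	P	2010	IDC G3, ER+, PR+, HER2-neg. Ki67-20%	IIIA	Mother’s side OC, 44; BC, 42; male BC, 50	BRCA2	yes (BSO 2010)
3	34	P	2007	IDC, ER+, PR+, HER2-neg	IIIA->IV	Father´s side, unk. primary, older age	BRCA1	no
4	35	P	1986	-	-	Mother’s side gyn. cancer in 70-s; Father’s side 2 unk. cancers in 40-s	BRCA1	no
5	37	I	2020	IDC G3, TNBC; Ki67-50%	IIIC	Mother, gyn. cancer, 40	BRCA1	yes (BSO 2021)
6	40	P	2014	IDC (m3), G3 ER-, PR-, HER2-pos	IIB	Mother’s side 2 unk. lethal malignancies in their 40-s; Father’s side BC, 50-s	CHEK2	no
7	41	I	2021	IDC; cT2N0M0; ER+, PR+; HER2-neg; Ki67-27%	IIA	Father´s side PC, 88; GC, 88	BRCA2	yes (BSO + MT 2021)
8	43	P	2016	-	-	Mother BC, 52 and OC, 60-s; mothers mother BC?	BRCA1	yes (BSO + MT 2017)
9	44	I	2019	Left breast: IDC, TNBC, Ki67->20%. Right breast: IDC G1 ER+, PR+, HER2-neg, Ki67-<10%	IA x2	Mother´s side PC, 56	BRCA1	yes (BSO 2019)
10	45	P	2013	-	-	Father´s side BC, 45; OC 50	BRCA1	no
11	47	P	2010	-	-	Mother´s side: BC, 37 + 62 contralateral, 50; OC, 55, 60, 60, 80	BRCA1	yes (BSO + MT 2011)
12	49	I	2021	IDC (m2) G1 + DCIS (multiple); Ki67-23%; ER+, PR+, HER2-neg	I, 0	Mother´s side BC, 44, 75 (mother and grandmother)	BRCA1	yes (BSO + MT 2021)
13	54	P	2014	IDC G3, TNBC	IA	Mother´s side GC, 64	BRCA1	no
14	59	I	2021	IDC G3, TNBC	IA	Mother´s side 3-cases of OC (2 at age 65, 1 NK)	BRCA1	yes (BSO 2021)
15	60	P	2007	ILC G3, ER+, PR+, HER2-neg. Ki67-30%	IA	Mother´s side BC, 80-s	BRCA1	no
16	62	P	2014	DCIS, Ki67-5%, ER+, PR+, HER2-neg	0	Father, GC, 40	BRCA1	no
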