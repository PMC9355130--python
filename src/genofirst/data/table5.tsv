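id	cancer_type	age_at_dx	status	year	morphology	stage	family_history	gene	surgery
1	Ovarian	47	P	2004	-	-	Mother’s side BC, 59, 35	BRCA1	no
2	Ovarian	60	P	2018	Serous carcinoma in both ovaries	IIIC	Father’s side GC, 61	BRCA1	no
3	Fallopian tube	51	P	2002	G3	IIIC	Sister BC, 45; Father´s side 1 unknown primary cancer	BRCA1	no
4	Kidney	47	I	2020	Chromophobe renal cell carcinoma	IA	Mother’s side: GC, 40s; Father’s side: PC, 61; BC, 80; PAC, 85	BRCA1	yes, (BSO 2021)
5	Kidney	46	P	2000	-	-	no	BRCA1	yes (BSO, 2020)
6	Salivary gland	60	P	2012	Adenocystic carcinoma; Ki67 20%	I	Mother BC, 45	CHEK2	no
7	Skin	43	P	2009	Basalioma	I	Father’s side GC, over 50	BRCA1	no
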