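cancer_location	lt40	age40_49	age50_59	gt59
Salivary gland	0	0	0	1
Skin	0	1	0	0
Breast	3	4	1	2
Ovary/adnex	0	0	2	1
Kidney	0	1	0	0
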