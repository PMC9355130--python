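table	row_id	breast	ovarian	prostate	pancreatic	gastric	male_breast	other
table4	1	3	2	0	0	0	0	0
table4	2	1	1	0	0	0	1	0
table4	3	0	0	0	0	0	0	1
table4	4	0	0	0	0	0	0	3
table4	5	0	0	0	0	0	0	1
table4	6	1	0	0	0	0	0	2
table4	7	0	0	1	0	1	0	0
table4	8	2	1	0	0	0	0	0
table4	9	0	0	1	0	0	0	0
table4	10	1	1	0	0	0	0	0
table4	11	3	4	0	0	0	0	0
table4	12	2	0	0	0	0	0	0
table4	13	0	0	0	0	1	0	0
table4	14	0	3	0	0	0	0	0
table4	15	1	0	0	0	0	0	0
table4	16	0	0	0	0	1	0	0
table5	1	2	0	0	0	0	0	0
table5	2	0	0	0	0	1	0	0
table5	3	1	0	0	0	0	0	1
table5	4	1	0	1	1	1	0	0
table5	5	0	0	0	0	0	0	0
table5	6	1	0	0	0	0	0	0
table5	7	0	0	0	0	1	0	0
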