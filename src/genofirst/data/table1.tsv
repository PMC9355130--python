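gene	rsid	refseq	cds	protein	cases	share_printed	clinvar_class
BRCA1	rs80357906	NM_007300	c.5329dupC	p.Gln1756Profs*74	31	52.5	KP
BRCA1	rs80357711	NM_007300	c.4035delA	p.Glu1346Lysfs*2	23	39	KP
BRCA1	rs80357282	NM_007300	c.1840A>T	p.Lys614*	4	6.8	KP
BRCA1	rs80357305	NM_007300	c.4258C>T	p.Gln1420*	1	1.7	KP
BRCA2	rs80359112	NM_000059	c.8572C>T	p.Gln2858*	22	88	KP
BRCA2	rs886040543	NM_000059	c.467_468insT	p.Lys157fs*26	2	8	KP
BRCA2	rs1555288494	NM_000059	c.9097_9098insT	p.Thr3033Ilefs*11	1	4	KP
CHEK2	rs555607708	NM_007194	c.1100delC	p.Thr367Metfs*15	9	60	KP
CHEK2	rs587782401	NM_007194	c.319+2T>A	NA	4	26.7	LP
CHEK2	rs121908698	NM_007194	c.444+1G>A	NA	2	13.3	KP
ATM	rs587782652	NM_000051	c.8147T>C	p.Val2716Ala	1	16.7	KP
ATM	rs780905851	NM_000051	c.8565T>G	p.Ser2855Arg	1	16.7	LP
ATM	rs758081262	NM_000051	c.2554C>T	p.Gln852*	2	33.3	KP
ATM	rs730881336	NM_000051	c.742C>T	p.Arg248*	2	33.3	KP
NBN	rs587776650	NM_002485	c.657_661delACAAA	p.Lys219Asnfs*16	2	100	KP
NF1	rs772295894	NM_000267	c.6792C>G	p.Tyr2264*	1	100	KP
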