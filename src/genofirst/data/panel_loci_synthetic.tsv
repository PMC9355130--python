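# Synthetic GRCh37 loci for the 16-variant panel. The published table gives
# rs IDs and HGVS names only; positions here are placeholders placed inside
# the correct gene bounds and are used purely as (chrom,pos,ref,alt) join
# keys between the genotype matrices and the ClinVar-style table.
rsid	gene	chrom	pos	ref	alt
rs80357906	BRCA1	17	41209082	A	AC
rs80357711	BRCA1	17	41224500	CA	C
rs80357282	BRCA1	17	41245600	A	T
rs80357305	BRCA1	17	41223000	C	T
rs80359112	BRCA2	13	32945100	C	T
rs886040543	BRCA2	13	32900400	T	TT
rs1555288494	BRCA2	13	32953600	A	AT
rs555607708	CHEK2	22	29091857	TC	T
rs587782401	CHEK2	22	29130300	T	A
rs121908698	CHEK2	22	29121300	G	A
rs587782652	ATM	11	108216180	T	C
rs780905851	ATM	11	108218000	T	G
rs758081262	ATM	11	108139000	C	T
rs730881336	ATM	11	108115500	C	T
rs587776650	NBN	8	90983441	CTTTGT	C
rs772295894	NF1	17	29663350	C	G
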