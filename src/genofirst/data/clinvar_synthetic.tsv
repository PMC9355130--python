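# Synthetic mini ClinVar-style assertion table covering the 16-variant panel,
# modeled on variant_summary columns and keyed by the synthetic GRCh37 loci of
# panel_loci_synthetic.tsv. Clinical significance strings follow the ClinVar
# dialect; no live database is consulted.
chrom	pos	ref	alt	gene	clinical_significance	review_status
17	41209082	A	AC	BRCA1	Pathogenic	reviewed by expert panel
17	41224500	CA	C	BRCA1	Pathogenic	reviewed by expert panel
17	41245600	A	T	BRCA1	Pathogenic	criteria provided, multiple submitters, no conflicts
17	41223000	C	T	BRCA1	Pathogenic	criteria provided, multiple submitters, no conflicts
13	32945100	C	T	BRCA2	Pathogenic	reviewed by expert panel
13	32900400	T	TT	BRCA2	Pathogenic	criteria provided, single submitter
13	32953600	A	AT	BRCA2	Pathogenic	criteria provided, single submitter
22	29091857	TC	T	CHEK2	Pathogenic	criteria provided, multiple submitters, no conflicts
22	29130300	T	A	CHEK2	Likely pathogenic	criteria provided, multiple submitters, no conflicts
22	29121300	G	A	CHEK2	Pathogenic	criteria provided, multiple submitters, no conflicts
11	108216180	T	C	ATM	Pathogenic	criteria provided, multiple submitters, no conflicts
11	108218000	T	G	ATM	Likely pathogenic	criteria provided, single submitter
11	108139000	C	T	ATM	Pathogenic	criteria provided, multiple submitters, no conflicts
11	108115500	C	T	ATM	Pathogenic	criteria provided, multiple submitters, no conflicts
8	90983441	CTTTGT	C	NBN	Pathogenic	reviewed by expert panel
17	29663350	C	G	NF1	Pathogenic	criteria provided, single submitter
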