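# Reference table: the five loci supported by every evidence layer (association,
# iHS selection, gene window scan, cis-eQTL), transcribed from a published
# RTK/ERK-pathway prostate-cancer study.  m = minor allele, M = major allele;
# iHS values refer to the ASN population; cis-eQTL gives the permutation P and
# the dataset in which it was observed.
snp	gene	allele	mm	Mm	MM	loci_ihs	gene_ihs	loci_p	gene_p	cis_eqtl
rs11238349	EGFR	A/G	21	362	1834	-2.751	0.07925	0.02387	0.12999	0.013(CEU)
rs17172438	EGFR	T/C	1	151	2273	1.912	0.07925	0.006644	0.12999	0.0382(YRI)
rs984654	EGFR	C/T	36	540	1848	-2.530	0.07925	0.02558	0.12999	1e-4(LCL)
rs11773818	EGFR	T/C	45	620	1759	-2.171	0.07925	0.01856	0.12999	0.0675(fibroblast)/<1e-4(LCL)
rs17172432	EGFR	T/C	9	353	1991	2.967	0.07925	0.001768	0.12999	0.0424(JPT)
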