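# Reference table: SNPs significant in the case-control association scan (P<0.05)
# and extreme in the iHS selection scan (|iHS|>1.65), transcribed from a published
# RTK/ERK-pathway prostate-cancer study (Asian case-control cohort; iHS per
# HapMap-II-derived panels for the ASN/CEU/YRI populations).  Unicode minus signs
# were converted to ASCII; empty gene flags are blank.
chr	snp	gene	or_	l95	u95	p	ihs_asn	ihs_ceu	ihs_yri	gene_asn	gene_ceu	gene_yri
7	rs11238349	EGFR	0.766	0.6078	0.9653	0.02387	-2.751	-1.532	NA	+
7	rs2302535	EGFR	0.7708	0.6121	0.9707	0.02693	-2.725	-1.503	NA	+
7	rs12535578	EGFR	0.7809	0.6206	0.9826	0.03486	-2.723	-1.734	NA	+
7	rs3800827	EGFR	0.801	0.6543	0.9806	0.03158	-2.538	-1.594	NA	+
7	rs984654	EGFR	0.8001	0.6579	0.9731	0.02558	-2.530	-1.498	NA	+
7	rs3735064	EGFR	0.7874	0.6429	0.9642	0.02077	-2.498	-1.635	-1.003	+
7	rs9642564	EGFR	0.8008	0.6535	0.9814	0.03226	-2.498	-1.635	NA	+
7	rs11766798	EGFR	0.8016	0.6539	0.9826	0.0333	-2.495	-0.906	NA	+
7	rs6978771	EGFR	0.793	0.6476	0.971	0.02475	-2.429	-1.804	NA	+
7	rs11773818	EGFR	0.8013	0.6663	0.9636	0.01856	-2.171	-0.908	NA	+
3	rs9818046	NA	0.7656	0.6098	0.9612	0.0214	-1.675	-0.236	0.343	+
7	rs3735062	EGFR	0.6426	0.4156	0.9934	0.04664	-1.653	NA	NA	+
7	rs17172432	EGFR	0.673	0.525	0.8626	0.001768	2.967	-0.416	0.457	+
7	rs17172434	EGFR	0.6899	0.5297	0.8984	0.005871	2.850	NA	0.020	+
15	rs6494584	NA	0.8549	0.7465	0.979	0.02338	2.233	NA	-0.050			+
11	rs7115260	NA	0.1387	0.02398	0.8024	0.0274	2.161	1.318	1.331
3	rs2255648	MKRN2	0.7628	0.6026	0.9655	0.02431	2.104	1.158	0.365	+
3	rs1542848	MKRN2	0.6941	0.5314	0.9068	0.007408	2.008	0.323	-0.056	+
7	rs17172438	EGFR	0.6003	0.4153	0.8678	0.006644	1.912	-0.424	-0.453	+
7	rs17172436	EGFR	0.6598	0.4401	0.989	0.04405	1.912	NA	0.769	+
7	rs3735063	EGFR	0.638	0.4246	0.9586	0.0305	1.908	NA	NA	+
3	rs2633442	MKRN2	0.7542	0.5822	0.9771	0.03272	1.893	0.850	-0.811	+
3	rs2442802	MKRN2	0.7669	0.5926	0.9925	0.04365	1.893	0.850	-0.811	+
7	rs10488140	EGFR	0.7337	0.5399	0.997	0.04782	1.824	-0.463	-0.139	+
16	rs2005219	BOLA2	0.7858	0.6737	0.9166	0.002144	1.750	0.874	0.211
3	rs2454431	NA	0.743	0.5746	0.9608	0.02354	1.722	-0.017	-1.581	+
7	rs6958497	EGFR	2.64	1.119	6.227	0.02663	1.647	NA	0.962	+
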