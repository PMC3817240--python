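# Reference cohort characteristics (1417 prostate-cancer cases, 1008 controls)
# transcribed from a published RTK/ERK-pathway prostate-cancer study.  Percentages
# in the source are computed over non-missing subjects per variable; "missing"
# rows carry the per-variable missing counts.
group	variable	category	count
case	total	all	1417
control	total	all	1008
case	psa	le4	55
case	psa	4to10	186
case	psa	ge10	1098
case	psa	missing	78
control	psa	le4	965
control	psa	4to10	32
control	psa	ge10	9
control	psa	missing	2
case	gleason	lt7	355
case	gleason	ge7	993
case	gleason	missing	69
case	clinical_stage	stage_0_I_II	727
case	clinical_stage	stage_III_IV	490
case	n_stage	n0	759
case	n_stage	n_ge1	369
case	m_stage	m0	810
case	m_stage	m_ge1	440
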