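snp_id	chrom	pos_bp	risk_allele	other_allele	odds_ratio	ci_95	p_value
rs2736100	5	1339516	C	A	1.29	1.25-1.34	2.34e-45
rs4977756	9	22058652	G	A	1.28	1.23-1.32	1.46e-41
rs498872	11	117982577	A	G	1.14	1.10-1.18	4.09e-11
rs6010620	20	61780283	G	A	1.34	1.29-1.40	2.81e-40
rs2297440	20	62312299	C	T	1.36	1.30-1.42	1.60e-42
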