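maternal_rsid	maternal_class	fetal_class	global_chi2	global_p	or	ci_low	ci_high	p	is_reference
rs649216	CC	AA/GA	11.308	0.010					1
rs649216	CC	GG			0.242	0.101	0.579	0.001	0
rs649216	CT/TT	AA/GA			0.496	0.216	1.138	0.098	0
rs649216	CT/TT	GG			0.471	0.147	1.506	0.204	0
rs1051456	CC	AA/GA			0.38	0.148	0.973	0.054	0
rs1051456	CC	GG			0.316	0.088	1.140	0.078	0
rs1051456	GC/GG	AA/GA	11.825	0.008					1
rs1051456	GC/GG	GG			0.292	0.120	0.662	0.003	0
rs34785252	CC	AA/GA			0.344	0.135	0.877	0.025	0
rs34785252	CC	GG			0.306	0.085	1.105	0.071	0
rs34785252	CA/AA	AA/GA	12.807	0.005					1
rs34785252	CA/AA	GG			0.283	0.124	0.642	0.003	0
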