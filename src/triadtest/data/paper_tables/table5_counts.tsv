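maternal_rsid	fetal_rsid	maternal_class	fetal_class	case	control
rs649216	rs9380142	CC	AA/GA	43	27
rs649216	rs9380142	CC	GG	10	26
rs649216	rs9380142	CT/TT	AA/GA	15	19
rs649216	rs9380142	CT/TT	GG	6	8
rs1051456	rs9380142	CC	AA/GA	9	15
rs1051456	rs9380142	CC	GG	4	8
rs1051456	rs9380142	GC/GG	AA/GA	49	31
rs1051456	rs9380142	GC/GG	GG	12	26
rs34785252	rs9380142	CC	AA/GA	9	16
rs34785252	rs9380142	CC	GG	4	8
rs34785252	rs9380142	CA/AA	AA/GA	49	30
rs34785252	rs9380142	CA/AA	GG	12	26
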