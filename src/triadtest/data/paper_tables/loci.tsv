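rsid	gene	major	minor
rs649216	KIR2DL4	C	T
rs1051456	KIR2DL4	C	G
rs34785252	KIR2DL4	C	A
rs9380142	HLA-G	G	A
rs1063320	HLA-G	C	G
rs1630185	HLA-G	A	G
rs1130363	HLA-G	G	A
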