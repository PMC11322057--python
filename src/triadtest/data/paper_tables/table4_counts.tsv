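rsid	group	stratum	allele1	allele2	n1	n2
rs9380142	case	all	G	A	19	10
rs9380142	case	mother	G	A	12	5
rs9380142	case	father	G	A	5	3
rs9380142	control	all	G	A	28	8
rs9380142	control	mother	G	A	14	4
rs9380142	control	father	G	A	14	4
rs1063320	case	all	C	G	14	24
rs1063320	case	mother	C	G	6	12
rs1063320	case	father	C	G	6	10
rs1063320	control	all	C	G	29	28
rs1063320	control	mother	C	G	11	8
rs1063320	control	father	C	G	14	16
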