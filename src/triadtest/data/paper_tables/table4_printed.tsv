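rsid	group	stratum	chi2	p
rs9380142	case	all	2.793	0.095
rs9380142	case	mother	2.882	0.09
rs9380142	case	father	0.5	0.48
rs9380142	control	all	11.111	0.001
rs9380142	control	mother	5.556	0.018
rs9380142	control	father	5.556	0.018
rs1063320	case	all	2.632	0.105
rs1063320	case	mother	2	0.157
rs1063320	case	father	1	0.317
rs1063320	control	all	0.018	0.895
rs1063320	control	mother	0.474	0.491
rs1063320	control	father	0.133	0.715
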