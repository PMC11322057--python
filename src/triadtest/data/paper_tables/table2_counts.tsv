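role	rsid	minor_case	total_case	minor_control	total_control	orient
mother	rs649216	23	148	31	160	T
mother	rs1051456	90	148	80	160	G
mother	rs34785252	62	148	75	160	A
mother	rs9380142	61	148	80	160	G
mother	rs1063320	53	148	60	160	G
mother	rs1630185	72	148	66	160	G
mother	rs1130363	73	148	66	160	A
father	rs9380142	45	112	52	156	A
father	rs1063320	48	112	72	156	G
father	rs1630185	56	112	97	156	A
father	rs1130363	56	112	97	156	G
offspring	rs9380142	85	148	62	160	A
offspring	rs1063320	74	148	57	160	G
offspring	rs1630185	61	148	75	160	G
offspring	rs1130363	62	148	68	160	A
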