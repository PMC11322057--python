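role	rsid	case_AA	case_AB	case_BB	ctrl_AA	ctrl_AB	ctrl_BB	collapse_wrt
mother	rs649216	53	19	2	53	23	4	minor
mother	rs1051456	13	32	29	23	34	23	major
mother	rs34785252	25	36	13	26	33	21	minor
mother	rs9380142	31	25	18	24	32	24	minor
mother	rs1063320	37	21	16	34	32	14	minor
mother	rs1630185	18	40	16	27	40	13	minor
mother	rs1130363	18	39	17	27	40	13	minor
father	rs9380142	25	17	14	37	30	11	minor
father	rs1063320	26	12	18	27	30	21	minor
father	rs1630185	18	20	18	28	41	9	minor
father	rs1130363	18	20	18	28	41	9	minor
offspring	rs9380142	16	31	27	34	30	16	minor
offspring	rs1063320	19	36	19	37	29	14	minor
offspring	rs1630185	24	39	11	20	45	15	minor
offspring	rs1130363	22	42	10	27	38	15	minor
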