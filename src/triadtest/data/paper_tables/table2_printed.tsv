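role	rsid	or	ci_low	ci_high	chi2	p
mother	rs649216	0.765	0.423	1.385	0.781	0.376
mother	rs1051456	1.551	0.986	2.44	2.854	0.056
mother	rs34785252	0.817	0.52	1.282	0.773	0.379
mother	rs9380142	1.426	0.908	2.238	2.389	0.122
mother	rs1063320	0.929	0.584	1.478	0.094	0.758
mother	rs1630185	1.349	0.859	2.117	1.701	0.192
mother	rs1130363	1.386	0.883	2.175	2.024	0.154
father	rs9380142	1.389	0.853	2.262	1.322	0.25
father	rs1063320	0.875	0.536	1.426	0.286	0.592
father	rs1630185	1.644	1.005	2.688	3.947	0.046
father	rs1130363	1.644	1.005	2.688	3.947	0.046
offspring	rs9380142	2.802	1.761	4.458	19.352	0.001
offspring	rs1063320	1.807	1.144	2.852	6.499	0.010
offspring	rs1630185	0.794	0.506	1.247	0.998	0.317
offspring	rs1130363	0.975	0.620	1.533	0.011	0.914
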