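role	rsid	p	dom_or	dom_lo	dom_hi	dom_p	rec_or	rec_lo	rec_hi	rec_p
mother	rs649216	0.725	0.778	0.392	1.544	0.473	0.528	0.094	2.970	0.468
mother	rs1051456	0.196	0.626	0.320	1.227	0.172	0.528	0.245	1.141	0.104
mother	rs34785252	0.406	0.944	0.482	1.847	0.866	0.599	0.599	1.305	0.197
mother	rs9380142	0.304	0.594	0.306	1.156	0.125	0.430	0.367	1.533	0.43
mother	rs1063320	0.314	0.739	0.391	1.396	0.351	1.300	0.585	2.892	0.519
mother	rs1630185	0.39	1.585	0.783	3.207	0.2	1.422	0.631	3.202	0.396
mother	rs1130363	0.347	1.585	0.783	3.207	0.2	1.537	0.688	3.434	0.295
father	rs9380142	0.254	1.119	0.562	2.229	0.749	2.030	0.843	4.889	0.114
father	rs1063320	0.106	1.182	0.571	2.446	0.652	1.464	0.729	2.942	0.284
father	rs1630185	0.010	1.182	0.571	2.446	0.652	3.632	1.487	8.868	0.005
father	rs1130363	0.010	1.182	0.571	2.446	0.652	3.632	1.487	8.868	0.005
offspring	rs9380142	0.010	2.196	1.009	4.780	0.047	1.633	0.736	3.622	0.227
offspring	rs1063320	0.029	2.491	1.259	4.927	0.009	1.629	0.748	3.544	0.219
offspring	rs1630185	0.555	0.694	0.344	1.401	0.309	0.757	0.323	1.773	0.521
offspring	rs1130363	0.477	1.204	0.610	2.378	0.593	0.677	0.283	1.618	0.38
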