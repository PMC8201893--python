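region	volume_mm3	expected_rate_pct	observed_count	observed_rate_pct	z	p_value	flag
Caudate	32353	1.4	18	1.8	0.953	0.341
Cerebellum	294552	12.8	214	20.9	7.745	9.80e-15
Frontal lobe	708087	30.7	277	27.0	-2.593	0.010
Insula	33041	1.4	12	1.2	-0.713	0.476
Occipital lobe	236954	10.3	84	8.2	-2.212	0.027
Parietal lobe	421103	18.3	170	16.6	-1.415	0.157
Putamen	26171	1.1	12	1.2	0.102	0.919
Temporal lobe	356227	15.5	115	11.2	-3.768	1.65e-4
Thalamus	34802	1.5	16	1.6	0.129	0.898
Deep white matter and brainstem	161082	7.0	108	10.5	4.440	9.04e-6
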