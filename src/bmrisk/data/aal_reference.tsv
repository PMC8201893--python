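region	volume_mm3	expected_rate_pct	observed_count	observed_rate_pct	z	p_value	flag
hippocampus	15024	0.79	7	0.68	-0.39	0.699
parahippocampus	16880	0.89	10	0.97	0.30	0.763
brainstem	40087	2.11	21	2.05	-0.13	0.896
caudatum	15648	0.82	7	0.68	-0.49	0.621
putamen	16584	0.87	7	0.68	-0.65	0.516
pallidum	4584	0.24	2	0.2	-0.30	0.765
pituitary gland	1088	0.06	0	0	-0.785	0.444
pineal gland	404	0.02	0	0	-0.467	0.641
amygdala	3744	0.19	0	0	-1.422	0.155	z_rate_rounding_inconsistent
precentral gyrus	55256	2.94	46	4.48	3.02	0.003	expected_rate_z_inconsistent
inferior frontal gyrus	84112	4.42	23	2.24	-3.39	6.971e-4
cingulate gyrus	61240	3.22	31	3.03	-0.35	0.724
occipital gyrus (superior, middle, inferior)	80616	4.23	31	3.0	-1.93	0.054
supramarginal gyrus	25840	1.36	5	0.49	-2.41	0.016
temporal pole	36520	1.92	12	1.17	-1.75	0.081
Heschl's gyrus	3792	0.19	3	0.29	0.67	0.503	z_rate_rounding_inconsistent
gyrus temporalis superior	43496	2.28	10	0.97	-2.81	0.005
gyrus temporalis medius	74808	3.93	29	2.82	-1.82	0.069
gyrus temporalis inferior	54056	2.83	21	2.05	-1.53	0.127
cerebellar hemispheres	104904	5.51	101	9.84	6.09	1.177e-9
vermis cerebelli	16320	0.86	10	0.98	0.41	0.683
cerebellar peduncle	74096	3.89	60	5.85	3.24	0.001
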