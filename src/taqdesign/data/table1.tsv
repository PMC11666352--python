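variant	round	rt90	rt116	rt201	rt526	k_rel	fidelity	dTdU_rate	t_opt	lna1_delay	lna2_delay	lna3_delay	kd	kcat_dT	kcat_dU	antibody_blocking	aptamer_blocking
E507K	I	−0.9	−1.89	4.65	6.85	0.25	5,205.19	1.00	64.00	2.78	1.19	4.41	3.38	27.66	23.60	Absent	Strong
M747Q	I	−0.81	−0.33	1.12	8.89	0.50	4,985.04	1.29	63.00	5.15	1.30	9.11	4.41	24.75	24.89	Absent	Strong
D578K	I	−0.73	1.22	0.55	6.76	0.15	5,140.39	1.16	62.75	2.16	1.44	6.81	4.20	19.39	10.57	Strong	Strong
D578N	I	−0.53	0.93	0.76	9.9	0.38	4,677.34	1.08	63.5	3.92	1.41	7.61	4.26	23.86	24.85	Absent	Strong
E507Q	I	−0.34	0.72	2.76	9.98	0.40	5,633.62	1.13	64.00	4.76	1.51	8.38	4.78	33.94	27.92	Absent	Strong
D578W	I	1.09	1.95	1.39	7.56	0.17	5,440.88	0.98	63.50	2.40	1.30	5.03	4.99	19.04	19.17	Strong	Strong
S515N	I	2.37	2.63	11.7	N/A	0.58	7,742.98	1.29	69.75	8.52	1.31	11.19	6.71	26.83	29.12	Strong	Strong
E507D	I	2.53	4.61	7.63	N/A	0.51	6,644.88	1.32	66.50	4.50	3.09	13.31	21.44	36.71	30.31	Absent	Strong
WT	I	4.44	5.34	15.29	14.33	1	5,986.21	1.29	72.25	4.68	1.66	10.67	6.19	35.56	32.99	Strong	Strong
F667Y	I	5.34	7.59	13.48	N/A	0.30	8,433.00	1.34	67.75	9.44	2.28	22.43	11.66	15.35	11.84	Weak	Strong
S515D	I	6.09	9.53	9.46	N/A	0.14	14,600.8	1.18	74.00	7.36	2.618	15.33	80.71	9.22	9.43	Strong	Strong
M747E	I	6.19	8.42	11.39	N/A	0.32	7,543.12	1.21	71.00	8.64	4.98	19.42	25.53	17.37	16.30	Strong	Weak
F667M	I	9.75	11.06	14.65	14.16	0.13	13,759.40	2.11	70.00	12.20	2.76	>30	8.79	7.00	1.75	Strong	Strong
H639Y	I	9.76	10.44	14.88	N/A	0.15	2,707.11	1.86	69.75	11.81	3.05	22.22	7.46	9.56	3.16	Strong	Strong
H639A	I	10.51	11.78	13.96	N/A	0.06	14,470.5	2.61	68.00	3.70	2.09	11.25	8.14	1.94	0.23	Strong	Strong
H639F	I	11.88	12.81	17.87	N/A	0.04	8,614.00	2.09	61.75	7.36	3.06	13.68	6.55	1.75	0.10	Strong	Strong
M747D	I	13.2	16.06	16.23	N/A	0.06	15,244.40	2.00	69.00	14.04	4.08	>40	29.63	4.61	2.18	Strong	Absent
S515F	I	14.05	15.48	N/A	N/A	0.07	6,114.36	1.66	72.75	1.34	2.23	9.31	211.11	10.00	10.00	N/A	Weak
F667A	I	16.12	18.05	N/A	N/A	0.02	42,014.30	2.38	71.00	10.36	2.14	23.43	11.14	0.39	0.12	Strong	Weak
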