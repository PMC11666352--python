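variant	round	rt90	rt116	rt201	rt526	k_rel	fidelity	dTdU_rate	lna3_delay	kd	antibody_blocking	aptamer_blocking	literature_selected	literature_data
E507Q-D578S-I614M	II	−1.01	−1.08	−0.87	8.9	0.50	1,921.59	1.39	1.87	1.17	Absent	Strong	no	
E742K-A743R	III	−0.95	−0.75	0.66	3.42	0.24	4,051.98	1.13	1.43	0.51	Weak	Weak	yes	Inhibitor resistance
E507K-D732N	II	−0.53	−0.67	0.08	12.22	0.17	3,696.37	0.97	1.91	1.69	Absent	Strong	no	
D732N	II	−0.51	−0.03	5.35	N/A	0.95	4,328.99	1.15	4.12	2.60	Strong	Strong	yes	Strand displacement, RT
D578H-M747Q	II	−0.47	0.3	0.2	N/A	0.25	3,634.96	0.88	3.08	3.29	Strong	Strong	no	
E507K-D578E	III	−0.41	0.32	2.14	12.54	0.54	4,636.97	0.93	3.80	1.07	Absent	Strong	no	
D578N-V783I	III	−0.15	−1.54	−0.37	10.57	0.36	2,537.75	1.01	2.23	2.19	Strong	Strong	no	
E507K-A570T-M747Q	III	−0.09	−1.4	0.42	8.29	0.51	4,147.97	1.09	2.85	1.53	Absent	Strong	no	
E507K-A570G-M747Q	III	−0.01	−1.56	0.34	7.82	0.79	4,459.81	0.89	3.20	5.15	Absent	Strong	no	
E507Q-S515N-D578S	II	0.89	1.59	3.06	12.16	0.40	3,966.74	1.95	2.33	2.91	Absent	Strong	no	
D578Q-D732N	III	1.23	1.46	2.92	18.32	0.21	4,334.18	1.07	5.42	0.80	Strong	Strong	no	
E708Q-D732N	III	1.34	0.14	3.58	7.17	0.77	4,382.99	1.06	5.77	4.33	Strong	Strong	no	
E507K-R536K-R660V	III	2.14	4.36	8.01	N/A	0.91	13,051.67	1.09	>40	0.79	Absent	Strong	yes	Allele specificity
S515N-M747S	II	2.84	1.49	3.01	8.9	0.43	4,150.20	0.68	4.47	1.93	Strong	Strong	no	
V586N-M747T	II	3.05	3.81	6.69	N/A	0.48	5,192.41	0.84	3.85	14.09	Strong	Strong	no	
E708L	III	3.32	4.44	6.97	N/A	0.86	5,164.52	1.23	8.27	6.82	Strong	Strong	yes	Inhibitor resistance
R660S	II	4.07	6.38	9.56	N/A	0.70	10,996.46	1.01	>30	10.64	Strong	Strong	yes	Allele specificity, decreased transition rate
E708D	III	5.14	5.99	8.75	N/A	1.40	5,000.88	1.11	8.78	4.51	Strong	Strong	yes	Cold sensitivity
E626K	III	5.26	5.47	8.87	24.13	0.25	5,228.77	0.69	12.14	5.74	Strong	Strong	yes	Inhibitor resistance, cold sensitivity
I707L	III	6.21	5.95	11.14	N/A	0.71	7,441.63	1.61	>40	8.54	Strong	Strong	yes	Cold sensitivity
R660V	III	6.96	10.07	12.58	14.01	1.04	15,402.44	1.69	>40	6.21	Strong	Strong	yes	Allele specificity
E507Q-D578S-R728Q	II	7.21	10.66	11.83	N/A	0.31	6,889.79	2.28	>40	6.29	Absent	Strong	no	
D578S-R728Q-M747Q	II	8.04	8.9	9.63	N/A	0.48	5,946.68	2.10	>40	10.35	Strong	Strong	no	
D578S-R728Q-M747V	II	8.20	11.54	14.2	13.78	0.24	6,346.44	2.49	>40	13.81	Strong	Strong	no	
S515D-K540M	II	9.90	11.49	13.93	N/A	0.01	28,816.50	2.03	N/A	>200	Strong	Strong	no	
R573K-D578N	III	11.33	14.53	N/A	N/A	0.08	7,828.28	3.57	>40	4.33	Weak	Weak	no	
E507R-R573K-E708Q	III	12.18	16.14	N/A	N/A	0.04	13,458.91	2.65	>40	0.96	Absent	Strong	no	
F667I-R728N-M747S	II	14.75	N/A	N/A	N/A	0.02	22,506.31	2.64	>40	14.38	Strong	Strong	no	
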