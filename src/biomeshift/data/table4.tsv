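clade	biome	d_single	sig_single	d_multiple	sig_multiple
Chionochloa	Forest	-0.28	False	1.28	False
Chionochloa	Open	1.18	False	1.22	False
Chionochloa	Alpine	1.15	False	1.50	False
Coprosma	Forest	0.62	False	0.55	True
Coprosma	Open	0.69	False	0.29	True
Coprosma	Alpine	-0.08	True	0.22	True
Melicytus	Forest	-2.58	True	-1.75	True
Melicytus	Open	-2.77	True	-2.47	True
Melicytus	Alpine	NA	False	2.45	False
Myrsine	Forest	0.82	False	-1.45	False
Myrsine	Open	1.24	False	1.43	False
Myrsine	Alpine	-1.19	False	-1.00	False
Poa X	Forest	-4.83	False	0.77	False
Poa X	Open	1.02	False	1.12	False
Poa X	Alpine	1.01	False	0.72	False
Pseudopanax	Forest	0.67	False	NA	False
Pseudopanax	Open	0.65	False	1.14	False
Pseudopanax	Alpine	NA	False	1.36	False
Rytidosperma A	Forest	NA	False	3.20	False
Rytidosperma A	Open	0.17	False	-0.17	False
Rytidosperma A	Alpine	0.12	False	0.30	False
Rytidosperma B	Forest	NA	False	NA	False
Rytidosperma B	Open	2.94	False	2.58	False
Rytidosperma B	Alpine	2.6	False	0.61	False
Veronica	Forest	1.07	False	0.40	True
Veronica	Open	0.65	False	1.21	False
Veronica	Alpine	0.39	True	0.48	True
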