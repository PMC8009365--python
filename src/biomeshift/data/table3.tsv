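clade	rate_single	sd_single	rate_multiple	sd_multiple	p_single	p_multiple	sig_single	sig_multiple	tendency_printed
Chionochloa	0.73	0.05	1.05	0.07	0.40	0.44	False	False	+0.04 (10%)
Coprosma	0.56	0.04	0.74	0.05	0.58	0.85	False	False	+0.27 (47%)
Melicytus	0.18	0.03	0.55	0.07	0.98	0.98	True	True	0.00 (0%)
Myrsine	0.27	0.06	0.55	0.05	0.00	0.35	False	False	+0.35 (N/A)
Poa X	0.62	0.05	0.72	0.07	0.69	0.95	False	True	+0.26 (38%)
Pseudopanax	0.31	0.05	0.54	0.04	0.83	0.32	False	False	-0.51 (61%)
Rytidosperma A	0.86	0.13	1.29	0.16	0.81	0.22	False	False	-0.59 (73%)
Rytidosperma B	0.57	0.12	0.86	0.14	0.58	0.89	False	False	+0.31 (53%)
Veronica	0.49	0.04	0.78	0.05	0.70	0.56	False	False	-0.14 (20%)
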