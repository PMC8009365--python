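clade	n_total	n_included	stem_age	crown_age	div_mode	rate_printed	life_form
Chionochloa	23	22	19.95	8.60	stem	0.16	Grass
Coprosma	55	54	25.48	13.73	stem	0.16	Woody
Melicytus	14	11	28.21	11.02	stem	0.09	Woody
Myrsine	11	11	11.81	9.98	stem	0.2	Woody
Poa X	29	29	3.55		stem	0.95	Grass
Pseudopanax	13	13	39.8	39.78	stem	0.06	Woody
Rytidosperma A	7	7	3.85	3.10	stem	0.5	Grass
Rytidosperma B	7	7		2.00	crown	0.63	Grass
Veronica	124	51	10.21	7.62	stem	0.47	Woody
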