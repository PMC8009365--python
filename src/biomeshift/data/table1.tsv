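study	location	clade	clade_size	specialists	specialists_pct_printed	multiple_biomes	shift_count	censored	rate_printed	focal
Cardillo et al. 2017	Australia	Hakea	151	113	75	True	47	False	0.31	False
Crisp et al. 2009	Southern Hemisphere	45 taxa	11000			False	396	False	0.04	False
Cruz et al. 2017	Brazil	Cryptanthus	48			False	4	False	0.08	False
Gagnon et al. 2019	Global	Caesalpinia Group	168	144	86	True	24	False	0.14	False
Gamisch et al. 2016	Madagascar	Bulbophyllum	30	26	87	True	21	False	0.7	False
Holstein & Renner 2011	Africa	Coccinia	27			False	6	False	0.22	False
Jara-Arancio et al. 2014	Western South America	Leucornye	17	13	76	False	2	False	0.11	False
Simon et al. 2009	South America	Andira	25	20	80	False	2	False	0.04	False
Simon et al. 2009	South America	Lupinus	94	93	99	False	1	False	0.01	False
Simon et al. 2009	South America	Mimosa	255	223	87	False	11	False	0.04	False
Simon et al. 2009	South America	Microlicieae	60	54	90	False	1	False	0.02	False
Spriggs et al. 2015	Northern Hemisphere	Viburnum	138			False	10	True	0.07	False
Toon et al. 2015	Australia	Triondiinae	66	51	77	True	15	True	0.23	False
Weeks et al. 2014	Global	Anacardiaceae	169	164	97	True	74	False	0.44	False
Weeks et al. 2014	Global	Burseraceae	136	132	97	True	11	False	0.08	False
Zizka et al. 2020	The Tropics	Bombacoideae	174	73	42	True	84	False	0.48	False
This study	New Zealand	Chionochloa	22	12	55	True	23	False	1.04	True
This study	New Zealand	Coprosma	54	30	56	True	40	False	0.74	True
This study	New Zealand	Melicytus	11	7	64	True	6	False	0.54	True
This study	New Zealand	Myrsine	11	5	45	True	6	False	0.54	True
This study	New Zealand	Poa X	29	20	69	True	21	False	0.72	True
This study	New Zealand	Pseudopanax	13	4	31	True	7	False	0.54	True
This study	New Zealand	Rytidosperma A	7	3	43	True	9	False	1.29	True
This study	New Zealand	Rytidosperma B	7	4	57	True	6	False	0.86	True
This study	New Zealand	Veronica	51	23	45	True	40	False	0.78	True
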