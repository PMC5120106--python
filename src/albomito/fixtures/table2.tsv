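region	population	N	A1a1a1	A1a2	A1b	A2	A3	others	A1a1a1_printed	A1a2_printed	A1b_printed	A2_printed	A3_printed	others_printed
America	USA (New Jersey)	30	28	0	0	0	0	2	0.93	0	0	0	0	0.07
America	USA (California)	49	0	29	5	0	0	15	0	0.59	0.10	0	0	0.31
America	USA (Texas)	31	24	0	2	0	0	5	0.77	0	0.07	0	0	0.16
America	USA (Hawaii)	32	0	27	0	0	0	5	0	0.84	0	0	0	0.16
America	Costa Rica	57	29	0	0	0	0	28	0.51	0	0	0	0	0.49
America	Panama	16	13	3	0	0	0	0	0.81	0.19	0	0	0	0
America	Brazil	134	0	0	134	0	0	0	0	0	1.0	0	0	0
Europe	Italy (Trento)	32	10	20	0	0	0	2	0.31	0.63	0	0	0	0.06
Africa	Cameroon	153	0	0	153	0	0	0	0	0	1.0	0	0	0
Asia	China	61	0	39	0	0	0	22	0	0.64	0	0	0	0.36
Asia	China (strain)	30	0	23	0	0	0	7	0	0.77	0	0	0	0.23
Asia	Japan	15	0	15	0	0	0	0	0	1.00	0	0	0	0
Asia	Taiwan	30	0	4	0	0	0	26	0	0.13	0	0	0	0.87
Asia	Thailand	10	0	0	10	0	0	0	0	0	1.00	0	0	0
Asia	Malaysia	77	0	0	77	0	0	0	0	0	1.00	0	0	0
Asia	Singapore	36	0	19	15	0	0	2	0	0.53	0.42	0	0	0.05
Asia	Indonesia (Java)	8	0	0	0	8	0	0	0	0	0	1.00	0	0
Asia	Indonesia (Timor-Leste)	17	0	0	0	17	0	0	0	0	0	1.00	0	0
Oceania	Australia (Torres Strait)	115	0	0	42	72	0	1	0	0	0.36	0.63	0	0.01
Oceania	Papua New Guinea	170	0	0	162	8	0	0	0	0	0.95	0.05	0	0
Oceania	Papua New Guinea (Southern Fly)	67	0	0	32	35	0	0	0	0	0.48	0.52	0	0
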