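seq_num	name	leaf_id	continent	place	haplogroup	accession	type_i_repeats	type_ii_repeats
1	Rim1	Rim1	Europe	Italy, Rimini	A1a1a1	KX383916	7	5
2	Vir1	Vir1	America	US, Virginia	A1a1a1a1	KX383917	N.D.	6
3	Rc1	Rc1	Europe	Italy, Reggio Calabria	A1a1a1a1	KX383918	N.D.	6
4	Vir2	Vir2	America	US, Virginia	A1a1a1a1	KX383919	N.D.	6
5	Ces1	Ces1	Europe	Italy, Cesena	A1a1a1a1	KX383920	N.D.	6
6	Cas1	Cas1	Europe	Italy, Cassino	A1a1a1a	KX383921	N.D.	6
7	Pav3	Pav3	Europe	Italy, Pavia	A1a1a1a	KX383922	N.D.	6
8	Ces2	Ces2	Europe	Italy, Cesena	A1a1	KX383923	N.D.	4
9	Bra	Bra	America	Brazil	A1b	KX383924	N.D.	N.D.
10	Lam2	Lam2	Asia	Thailand, Lampang, Hang Chat	A1b1a	KX383925	N.D.	3
11	Ban7	Ban7	Asia	Thailand, Uthai Thani, Ban Rai	A1b1a	KX383926	N.D.	3
12	Ath1	Ath1	Europe	Greece, Athens	A1b1a	KX383927	N.D.	3
13	Chu3	Chu3	Asia	Thailand, Chumphon, Phato	A1b1	KX383928	N.D.	3
14	Rim4	Rim4	Europe	Italy, Rimini	A1a2a1	KX383929	N.D.	4
15	Tir1	Tir1	Europe	Albania, Tirana	A1a2a1	KX383930	N.D.	4
16	Tir2	Tir2	Europe	Albania, Tirana	A1a2a1	KX383931	N.D.	4
17	-	KR068634	Asia	China, Jiangsu, Nanjing	A1a2a1	KR068634	5	4
18	Ath2	Ath2	Europe	Greece, Athens	A1a2a	KX383932	N.D.	4
19	Pav4	Pav4	Europe	Italy, Pavia	A1a2a	KX383933	N.D.	4
20	Fo2	Fo2	Asia	China, Foshan	A1a2	KX383934	N.D.	4
21	Los1	Los1	Asia	Philippines, Laguna, Los Banos	A2a	KX383935	N.D.	3
22	Los2	Los2	Asia	Philippines, Laguna, Los Banos	A2a	KX809761	N.D.	3
23	Los3	Los3	Asia	Philippines, Laguna, Los Banos	A2a	KX809762	N.D.	3
24	Los5	Los5	Asia	Philippines, Laguna, Los Banos	A2a	KX809764	N.D.	3
25	Los4	Los4	Asia	Philippines, Laguna, Los Banos	A2	KX809763	N.D.	3
26	J-Wa1	J-Wa1	Asia	Japan, Wakayama	A1a1a	KX809765	N.D.	4
27	-	NC006817	Asia	Taiwan, Taipei	A3	NC006817	5	4
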