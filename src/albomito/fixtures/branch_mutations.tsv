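branch	mutation	annotation_only
A1	8790@	0
A1	12043@	0
A1a	4521@	0
A1a	9918@	0
A1a1	5610@	0
A1a1a	10377@	0
A1a1a1	1536@	0
A1a1a1	2165@	0
A1a1a1	6088@	0
A1a1a (Japanese motif)	2435	0
A1a1a (Japanese motif)	11200	0
A1a1a (Japanese motif)	13642	0
A1a1a1a	2015	0
A1a1a1a	9050	0
Cas1	4710	0
Pav3	12355	0
A1a1a1a1	1823	0
A1a1a1a1	12980	0
A1a1a1a1-I	9502	0
Vir1	3301	0
Rc1	13077	0
A1a2	2300	0
A1a2	5872	0
Fo2	13220	0
A1a2a	3407	0
Ath2	6777	0
Pav4	10645	0
Pav4	4890h	1
A1a2a1	9981	0
Rim4	621	0
KR068634	2550	0
KR068634	4466	0
A1b	1754	0
A1b	10811	0
A1b (Brazilian motif)	7210	0
A1b (Brazilian motif)	13554	0
A1b1	4204	0
A1b1	887d	0
Chu3	8825	0
A1b1a	12166	0
Lam2	890	0
Ban7	14202	0
Ath1	6245	0
A2	1990	0
A2	3666	0
Los4	9123	0
A2a	5489	0
A2a	14321.1	1
Los1	702	0
Los5	13909	0
KR068634	15850	1
KR068634	15910	1
KR068634	15970	1
KR068634	16210	1
KR068634	16270	1
KR068634	16330	1
KR068634	16390	1
KR068634	16450	1
KR068634	16510	1
KR068634	16570	1
NC006817	15850	1
NC006817	15910	1
NC006817	15970	1
NC006817	16210	1
NC006817	16270	1
NC006817	16330	1
NC006817	16390	1
NC006817	16450	1
NC006817	16510	1
NC006817	16570	1
NC006817	16650	1
NC006817	16710	1
NC006817	16770	1
A3	1503	0
A3	1578C	0
A3	1676C	0
A3	1704	0
A3	1964	0
A3	2550	0
A3	101	0
A3	137	0
A3	174	0
A3	210	0
A3	246	0
A3	283	0
A3	319	0
A3	355	0
A3	392	0
A3	428	0
A3	464	0
A3	501	0
A3	537	0
A3	573	0
A3	609	0
A3	647	0
A3	683	0
A3	720	0
A3	757	0
A3	793	0
A3	829	0
A3	866	0
A3	904	0
A3	940	0
A3	977	0
A3	1013	0
A3	1049	0
A3	1086	0
A3	1122	0
A3	1158	0
A3	1195	0
A3	1231	0
A3	1267	0
A3	1304	0
A3	1340	0
A3	1376	0
A3	1413	0
A3	1449	0
A3	2636	0
A3	2673	0
A3	2709	0
A3	2745	0
A3	2781	0
A3	2818	0
A3	2854	0
A3	2890	0
A3	2927	0
A3	2963	0
A3	2999	0
A3	3036	0
A3	3072	0
A3	3108	0
A3	3145	0
A3	3181	0
A3	3217	0
A3	3254	0
A3	3290	0
A3	3327	0
A3	3364	0
A3	3400	0
A3	3437	0
A3	3474	0
A3	3510	0
A3	3546	0
A3	3583	0
A3	3619	0
A3	3655	0
A3	3692	0
A3	3729	0
A3	3765	0
A3	3801	0
A3	3839	0
A3	3875	0
A3	3911	0
A3	3948	0
A3	3984	0
A3	4020	0
A3	4057	0
A3	4093	0
A3	4129	0
A3	4166	0
A3	4202	0
A3	4239	0
A3	4276	0
A3	4312	0
A3	4348	0
A3	4385	0
A3	4421	0
A3	4457	0
A3	4495	0
A3	4532	0
A3	4568	0
A3	4604	0
A3	4641	0
A3	4677	0
A3	4714	0
A3	4751	0
A3	4787	0
A3	4823	0
A3	4860	0
A3	4897	0
A3	4933	0
A3	4970	0
A3	5006	0
A3	5042	0
A3	5079	0
A3	5115	0
A3	5151	0
A3	5188	0
A3	5224	0
A3	5260	0
A3	5297	0
A3	5333	0
A3	5369	0
A3	5406	0
A3	5442	0
A3	5478	0
A3	5516	0
A3	5552	0
A3	5588	0
A3	5625	0
A3	5662	0
A3	5698	0
A3	5734	0
A3	5771	0
A3	5807	0
A3	5843	0
A3	5881	0
A3	5917	0
A3	5953	0
A3	5990	0
A3	6026	0
A3	6062	0
A3	6100	0
A3	6136	0
A3	6172	0
A3	6209	0
A3	6246	0
A3	6282	0
A3	6319	0
A3	6355	0
A3	6391	0
A3	6428	0
A3	6464	0
A3	6500	0
A3	6536	0
A3	6573	0
A3	6609	0
A3	6645	0
A3	6682	0
A3	6718	0
A3	6754	0
A3	6792	0
A3	6828	0
A3	6864	0
A3	6901	0
A3	6937	0
A3	8224	0
A3	8261	0
A3	8297	0
A3	8333	0
A3	8370	0
A3	8406	0
A3	8442	0
A3	8479	0
A3	8515	0
A3	8551	0
A3	8588	0
A3	8624	0
A3	8660	0
A3	8696	0
A3	8733	0
A3	8769	0
A3	8806	0
A3	8844	0
A3	8880	0
A3	8916	0
A3	8953	0
A3	8989	0
A3	9025	0
A3	9063	0
A3	9099	0
A3	9136	0
A3	9173	0
A3	9209	0
A3	9245	0
A3	9282	0
A3	9318	0
A3	9354	0
A3	9391	0
A3	9427	0
A3	9463	0
A3	9500	0
A3	9537	0
A3	9573	0
A3	9610	0
A3	9646	0
A3	9682	0
A3	9718	0
A3	9755	0
A3	9791	0
A3	9827	0
A3	9864	0
A3	9900	0
A3	9937	0
A3	9974	0
A3	10011	0
A3	10047	0
A3	10084	0
A3	10120	0
A3	10156	0
A3	10193	0
A3	10229	0
A3	10265	0
A3	10302	0
A3	10338	0
A3	10374	0
A3	10412	0
A3	10448	0
A3	10484	0
A3	10521	0
A3	10557	0
A3	10593	0
A3	10629	0
A3	10667	0
A3	10703	0
A3	10739	0
A3	10776	0
A3	10813	0
A3	10849	0
A3	10886	0
A3	10922	0
A3	10958	0
A3	10995	0
A3	11031	0
A3	11067	0
A3	11104	0
A3	11140	0
A3	11176	0
A3	11214	0
A3	11250	0
A3	11286	0
A3	11323	0
A3	11359	0
A3	11395	0
A3	11432	0
A3	11468	0
A3	11504	0
A3	11541	0
A3	11577	0
A3	11613	0
A3	11649	0
A3	11686	0
A3	11722	0
A3	11758	0
A3	11795	0
A3	11831	0
A3	11867	0
A3	11904	0
A3	11940	0
A3	11976	0
A3	12013	0
A3	12050	0
A3	12086	0
A3	12123	0
A3	12159	0
A3	12196	0
A3	12233	0
A3	12269	0
A3	12305	0
A3	12342	0
A3	12379	0
A3	12415	0
A3	12452	0
A3	12488	0
A3	12524	0
A3	12560	0
A3	12597	0
A3	12633	0
A3	12669	0
A3	12706	0
A3	12742	0
A3	12778	0
A3	12815	0
A3	12851	0
A3	12887	0
A3	12924	0
A3	12960	0
A3	12997	0
A3	13034	0
A3	13070	0
A3	13107	0
A3	13144	0
A3	13180	0
A3	13216	0
A3	13254	0
A3	13290	0
A3	13326	0
A3	13363	0
A3	13399	0
A3	13435	0
A3	13471	0
A3	13508	0
A3	13544	0
A3	13581	0
A3	13618	0
A3	13655	0
A3	13691	0
A3	13728	0
A3	13764	0
A3	13800	0
A3	13837	0
A3	13873	0
A3	13910	0
A3	13947	0
A3	13983	0
A3	14019	0
A3	14056	0
A3	14092	0
A3	14128	0
A3	14165	0
A3	14201	0
A3	14238	0
A3	14275	0
A3	14311	0
A3	14348	0
A3	14385	0
A3	14421	0
A3	14457	0
A3	14493	0
A3	14530	0
A3	14566	0
A3	14602	0
A3	14639	0
A3	14675	0
A3	14711	0
A3	14748	0
A3	14784	0
A3	14820	0
A3	14857	0
A3	14893	0
A3	14969	0
A3	15159	0
A3	15349	0
A3	16832A	0
A3	17139A	0
A3	14935	0
A3	15020	0
A3	15075	0
A3	15230	0
A3	15290	0
A3	15410	0
A3	15520	0
A3	15610	0
A3	15700	0
A3	16020	0
A3	16150	0
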