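label	pct_ever_screened_mean	pct_ever_screened_sd	n_screens_mean	n_screens_sd	deaths_avoided_mean	deaths_avoided_sd	nns_mean	nns_sd	life_years_saved_mean	life_years_saved_sd
T60-75-40-10	11.1	1.0	42893	2757	153	72	94	64	1896	1093
T60-80-40-10	11.2	1.0	45685	3223	173	78	85	60	1883	1201
B60-85-40-10	11.3	1.1	69662	4466	256	115	59	44	2771	1639
T60-85-40-15	12.0	1.2	55316	3573	201	93	77	52	2085	1426
T60-80-40-20	12.6	1.0	56712	3502	197	88	81	52	2138	1344
B60-85-40-20	12.7	1.0	88781	4802	288	138	57	37	2943	1957
T60-80-40-25	12.9	0.9	60570	3483	202	92	80	47	2299	1352
T60-85-40-25	13.0	0.9	66333	3578	225	106	73	44	2344	1559
A60-85-40-25	13.0	0.9	185451	8027	449	219	38	25	4394	2859
A55-85-40-15	13.7	0.8	200575	10864	445	223	41	29	4740	2844
T55-85-40-25	13.9	0.9	83043	4633	252	120	70	44	2767	1702
A55-85-40-20	14.0	0.9	220505	10542	485	237	38	26	4958	3029
B50-80-40-25	14.5	0.6	137944	6221	358	167	51	32	4012	2216
B50-85-40-25	14.6	0.7	143621	6835	376	178	49	30	4090	2377
A50-85-40-25	14.6	0.7	281218	11061	542	261	35	22	5955	3161
A60-85-30-10	15.6	1.0	180599	7772	412	200	50	34	4212	2603
A60-85-30-15	16.9	1.1	213400	8568	457	232	49	32	4666	2964
B60-85-30-20	17.9	1.2	127046	4888	358	166	64	41	3591	2304
A60-85-20-10	18.3	1.0	214153	7742	452	218	53	35	4613	2839
A55-80-30-15	19.3	1.0	286813	11098	521	268	49	31	5603	3278
A55-85-30-20	20.2	0.8	331990	11705	593	305	44	27	6237	3642
A55-85-30-25	20.4	0.9	361001	11107	628	323	42	25	6469	3822
A50-85-30-15	21.2	0.7	382439	15625	608	316	45	27	6998	3596
A50-85-30-20	21.4	0.8	419782	15070	653	336	42	25	7244	3781
A45-85-30-25	22.0	0.7	520793	18498	707	362	39	22	7775	3959
B60-85-20-20	23.2	1.0	158397	4474	399	185	73	44	4070	2508
A60-85-20-25	24.8	1.0	348894	6919	624	314	51	30	6120	3857
A55-80-20-20	26.6	0.9	410565	10425	631	342	55	32	6928	3892
B55-85-20-25	27.4	1.1	247058	6305	501	256	69	39	5256	3153
A50-85-20-15	27.9	0.9	496010	15834	685	378	53	30	7688	4118
A60-85-10-20	28.0	2.0	370825	19139	605	296	59	34	6108	3671
A50-85-20-20	28.7	1.0	557513	15580	737	411	50	28	8028	4450
A50-85-20-25	29.0	0.9	610443	14822	787	427	47	25	8746	4512
A45-80-20-25	29.9	1.1	721956	19536	780	453	49	25	9206	4531
A55-85-10-15	29.9	2.3	448193	26722	651	332	59	34	6876	3909
A60-85-10-25	31.1	2.1	427669	21334	660	322	59	32	6474	3951
A50-80-10-15	34.6	2.3	583756	35681	700	388	63	34	8036	4143
A55-85-10-25	36.0	2.0	590101	31172	768	397	59	31	8109	4454
A50-85-10-20	37.5	2.0	685484	39445	795	422	59	31	8772	4509
A50-85-10-25	38.9	1.9	767313	40320	851	443	57	28	9151	4735
A45-80-10-25	40.3	1.9	920505	45739	846	479	60	29	9851	4737
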