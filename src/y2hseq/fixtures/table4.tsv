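# TPL-N vs EMPTY screen: SNR-ranked candidate interactors (printed table, comma-decimal dialect)
# flagged = italicized row (empty count imputed); known = bold gene id (previously reported interactor)
# ear values: Y = EAR motif reported; Y* = EAR motif in the wrong frame or an untranslated region (bold Y in print)
# rank numbering is as printed (15 is skipped in the source numbering; max rank 51)
rank	gene_id	length_bp	fpkm_empty	fpkm_bait	snr	alias	full_length	ear	flagged	known
1	AT5G25890	873	11,301	3997,602	353,736	IAA28/IAR2	Y	Y	0	1
2	AT3G23030	941	49,339	8581,581	173,933	IAA2	Y	Y	0	1
3	AT5G43700	1168	0,994	111,604	112,307	ATAUX2-11/IAA4	Y	Y	0	1
4	AT4G28640	1202	20,761	1121,873	54,037	IAA11	Y	Y	0	1
5	AT4G29080	1337	4,341	219,498	50,568	IAA27/PAP2	Y	Y	0	1
6	AT3G15540	970	7,180	266,613	37,135	IAA19/MSG2	Y	Y	0	1
7	AT1G04250	1087	249,863	8692,277	34,788	AXR3/IAA17	Y	Y	0	1
8	AT3G50000	1467	19,384	543,833	28,055	ATCKA2	Y		0	0
9	AT2G33310	1820	64,093	1054,613	16,454	IAA13	Y	Y	0	1
10	AT2G46990	655	9,746	158,039	16,215	IAA20	Y	Y	0	0
11	AT5G13790	962	15,685	198,181	12,635	AGL15	Y	Y	0	1
12	AT3G54390	1341	3,0294	69,6555	22,9933		Y		0	0
13	AT4G37940	715	0,8117	15,1114	18,6177	AGL21	Y		1	1
14	AT2G40260	1233	0,4707	8,1976	17,4165		Y		1	0
16	AT3G58820	1391	0,4172	5,2619	12,6120			Y*	1	0
17	AT1G51950	1539	4,9022	56,1646	11,4570	IAA18	Y	Y	0	1
18	AT1G04100	1254	1,3884	15,8426	11,4108	IAA10	Y	Y	0	1
19	AT3G05670	3090	0,9391	9,2492	9,8493			Y	0	0
20	AT4G31620	1809	0,9624	9,2481	9,6091			Y*	0	0
21	AT2G33550	1194	8,2629	77,0636	9,3265			Y	0	0
22	AT1G08290	1760	0,3297	2,9705	9,0085	WIP3			0	0
23	AT3G19860	1288	3,1540	25,7074	8,1506	bHLH121	Y		0	0
24	AT5G25160	959	1,2103	9,4494	7,8074	ZFP3	Y	Y	0	0
25	AT5G47110	1088	1,0668	8,3290	7,8074	LIL3:2			0	0
26	AT3G04730	1279	0,4537	3,5426	7,8074	IAA16		Y	0	0
27	AT5G04550	2580	0,2249	1,7562	7,8074				0	0
28	AT3G15760	843	0,6884	4,9614	7,2068		Y		0	0
29	AT1G12270	1949	0,5955	4,2919	7,2068	Hop1			0	0
30	AT3G47980	1097	0,5290	3,8126	7,2068			Y*	0	0
31	AT1G02650	1542	0,3764	2,7124	7,2068				0	0
32	AT2G38950	2482	0,2338	1,6851	7,2068				0	0
33	AT3G19070	1041	1,6725	11,7184	7,0066			Y*	0	0
34	AT1G28300	1317	0,8813	6,0868	6,9066	AtLEC2		Y*	0	0
35	AT3G56250	669	0,8675	5,7308	6,6063		Y		0	0
36	AT1G01030	1905	0,3046	2,0126	6,6063	NGA3		Y*	1	0
37	AT1G61900	1913	0,3034	2,0041	6,6063			Y*	0	0
38	AT1G79950	3123	0,1858	1,2276	6,6063				0	0
39	AT3G43575	4332	0,1340	0,8850	6,6063				0	0
40	AT5G36870	5616	0,2067	1,3033	6,3060	ATGSL09/atgsl9			0	0
41	AT2G30540	680	4,2672	26,6529	6,2459				0	0
42	AT2G38110	1845	4,0891	25,5028	6,2367	ATGPAT6		Y*	0	0
43	AT2G25180	1980	3,2241	19,8913	6,1695	ARR12/AtARR12		Y*	0	0
44	AT1G53030	530	1,0950	6,5762	6,0057				1	0
45	AT1G13680	1180	0,4918	2,9537	6,0057				1	0
46	AT4G19540	1215	0,4776	2,8686	6,0057	INDH/INDL	Y		1	0
47	AT3G56160	1600	0,3627	2,1784	6,0057				0	0
48	AT5G03570	1673	0,3469	2,0833	6,0057	ATIREG2/FPN2			1	0
49	AT3G59150	1866	0,3110	1,8678	6,0057		Y		0	0
50	AT4G03560	2674	0,2170	1,3034	6,0057	ATCCH1/ATTPC1/FOU2			1	0
51	AT3G03680	3308	0,1754	1,0536	6,0057				0	0
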