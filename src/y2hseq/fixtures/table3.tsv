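# NINJA vs EMPTY screen: SNR-ranked candidate interactors (printed table, comma-decimal dialect)
# flagged = italicized row (empty count imputed); known = bold gene id (previously reported interactor)
# rank numbering is as printed (15 and 61-69 are skipped in the source numbering; max rank 71)
rank	gene_id	length_bp	fpkm_empty	fpkm_bait	snr	alias	full_length	tify	flagged	known
1	AT3G17860	1588	0,731	1212,639	1659,075	JAI3/JAZ3/TIFY6B	Y	Y	0	1
2	AT1G19180	1329	27,074	20257,141	748,213	AtJAZ1/TIFY10A	Y	Y	0	1
3	AT1G74950	1280	4,081	2569,920	629,798	JAZ2/TIFY10B		Y	0	1
4	AT5G13220	1375	5,065	2735,323	540,063	JAS1/JAZ10/TIFY9	Y	Y	0	1
5	AT4G14713	1503	1,544	375,437	243,081	PPD1/TIFY4A	Y	Y	0	1
6	AT1G17380	1133	1,537	124,895	81,277	JAZ5/TIFY11A	Y	Y	0	1
7	AT4G14720	1568	3,701	294,079	79,455	PPD2/TIFY4B	Y	Y	0	1
8	AT4G36480	2058	0,282	28,960	102,697	ATLCB1/EMB2779			1	0
9	AT1G34340	1833	0,950	47,346	49,847				0	0
10	AT3G06850	1730	1,342	33,645	25,074	BCE2/DIN3/LTA1			0	0
11	AT4G05553	336	1,727	36,306	21,020		Y		0	0
12	AT5G47810	1684	4,480	64,989	14,506	PFK2	Y		0	0
13	AT3G03680	3308	0,175	2,213	12,612				0	0
14	AT3G15760	843	0,688	8,269	12,011		Y		0	0
16	AT3G02830	1695	0,342	4,113	12,011	PNT1/ZFN1	Y		0	0
17	AT2G34160	636	0,912	10,412	11,411		Y		1	0
18	AT4G17080	2053	0,283	3,056	10,810				0	0
19	AT3G06550	2145	0,271	2,762	10,210	RWA2			1	0
20	AT1G58150	276	2,103	20,205	9,609		Y		0	0
21	AT1G29890	1901	0,916	8,801	9,609	RWA4			0	0
22	AT2G33820	936	0,620	5,958	9,609	ATMBAC1	Y		0	0
23	AT1G73340	1711	0,339	3,259	9,609		Y		1	0
24	AT5G67440	2662	0,218	2,095	9,609	MEL2/NPY3			0	0
25	AT1G32440	1908	0,304	2,740	9,009	PKp3			0	0
26	AT3G49350	2220	0,261	2,355	9,009				1	0
27	AT2G44830	2399	0,242	2,179	9,009				0	0
28	AT5G27390	1040	1,116	9,719	8,708		Y		0	0
29	AT2G30105	1377	0,421	3,544	8,408				0	0
30	AT3G61790	1407	0,412	3,468	8,408				0	0
31	AT4G39140	1600	0,363	3,050	8,408				0	0
32	AT4G37880	1608	0,361	3,035	8,408				0	0
33	AT1G26260	1622	0,358	3,008	8,408	CIB5			0	0
34	AT4G02100	2085	0,278	2,340	8,408				0	0
35	AT5G16000	2323	0,250	2,101	8,408	AtNIK1			0	0
36	AT2G23450	2387	0,243	2,044	8,408				1	0
37	AT3G42660	2862	0,203	1,705	8,408				0	0
38	AT1G13370	648	0,896	6,992	7,807		Y		1	0
39	AT1G66670	1196	0,485	3,788	7,807	CLPP3/NCLPP3	Y		0	0
40	AT2G32340	1256	0,462	3,607	7,807		Y		0	0
41	AT1G10660	1648	0,352	2,749	7,807				0	0
42	AT3G16090	2120	0,274	2,137	7,807	AtHrd1A			0	0
43	AT4G12120	2404	0,241	1,885	7,807	ATSEC1B			0	0
44	AT3G23660	2568	0,226	1,764	7,807				0	0
45	AT1G31440	1870	0,621	4,660	7,507				0	0
46	AT3G44716	592	0,980	7,065	7,207		Y		0	0
47	AT3G60640	643	0,903	6,505	7,207	ATG8G	Y		0	0
48	AT2G34980	912	0,636	4,586	7,207	SETH1	Y		0	0
49	AT5G28330	974	0,596	4,294	7,207		Y		1	0
50	AT4G25600	1165	0,498	3,590	7,207				1	0
51	AT2G18162	1231	0,471	3,398	7,207	CPuORF1	Y		0	0
52	AT3G04730	1279	0,454	3,270	7,207	IAA16	Y		0	0
53	AT4G26070	1342	0,432	3,117	7,207	ATMEK1/MKK1N	Y		0	0
54	AT1G03687	1428	0,406	2,929	7,207				0	0
55	AT1G06910	1528	0,380	2,737	7,207	TRFL7			0	0
56	AT1G52630	1537	0,378	2,721	7,207		Y		1	0
57	AT1G18570	1654	0,351	2,529	7,207	AtMYB51/BW51A			0	0
58	AT2G33580	2239	0,259	1,868	7,207	LYK5			1	0
59	AT5G04550	2580	0,225	1,621	7,207				0	0
60	AT4G03560	2674	0,217	1,564	7,207	ATCCH1/ATTPC1			1	0
70	AT4G02020	2876	0,202	1,454	7,207	EZA1/SDG10			0	0
71	AT3G13690	3321	0,175	1,259	7,207				0	0
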