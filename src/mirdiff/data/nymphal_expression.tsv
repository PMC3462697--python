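mirna	counts_N5	rpkm_N5	counts_N6	rpkm_N6
bantam-3p	4355	5939.042	10724	24195.476
let-7-5p	6238	8608.982	10157	22754.573
miR-iab-4-5p	618	856.282	559	1253.199
miR-1-3p	1162418	1676872.803	1101990	2579427.475
miR-2-3p	16839	30473.966	20102	44802.071
miR-7-5p	1115	1603.854	764	1782.859
miR-8-3p	129951	173738.073	185336	401628.852
miR-8-5p	36142	50136.290	37104	83764.303
miR-9a-3p	1316	1810.390	990	2209.068
miR-9a-5p	7345	10519.521	6705	15734.350
miR-9b-3p	444	610.332	504	1151.966
miR-9c-5p	2436	3731.535	3748	9306.244
miR-10-3p	2018	2857.459	1542	3543.522
miR-10-5p	10308	14188.293	9746	21761.685
miR-12-5p	607	811.513	714	1543.625
miR-13a-3p	923	1268.955	946	2090.234
miR-13b-3p	2436	3124.586	2431	5064.433
miR-14-3p	89736	124156.170	52803	118969.680
miR-31-5p	5091	7007.565	5468	12172.024
miR-34-5p	3124	4465.801	2343	5457.763
miR-71-3p	5006	6984.393	3798	8620.928
miR-71-5p	31574	43472.049	28524	63933.294
miR-79-3p	186	277.628	504	1151.966
miR-87-3p	4999	7205.065	7177	16792.743
miR-92a-3p	529	722.703	450	1001.511
miR-92b-3p	1915	2632.691	1375	3066.353
miR-100-5p	5943	8211.876	11666	26310.508
miR-124-3p	406	608.142	325	792.840
miR-125-5p	5131	7347.148	9416	21901.480
miR-133-3p	1951	2682.100	1404	3130.094
miR-184-3p	106965	167335.182	85068	200902.694
miR-190-5p	2223	2898.137	440	935.079
miR-193-3p	340	472.188	319	724.041
miR-252-3p	1587	2175.501	25	56.778
miR-252-5p	20378	29676.940	19167	45269.029
miR-263a-5p	30064	38608.305	34005	70511.600
miR-263b-5p	1470	1918.685	1669	3538.234
miR-275-3p	6538	19349.775	8708	19144.342
miR-276-3p	133114	192096.386	176820	394590.630
miR-276-5p	662	902.984	28	54.987
miR-277-3p	3881	5345.294	4880	10875.555
miR-278-3p	588	851.690	636	1492.383
miR-279-3p	33581	47196.919	43314	99043.811
miR-281-3p	346	479.946	442	1001.721
miR-281-5p	2412	3298.680	2637	5834.284
miR-283-5p	1684	2362.825	1891	4289.933
miR-305-5p	4620	6304.241	3952	8866.733
miR-306-5p	45159	61925.032	32982	73346.550
miR-307-3p	1829	2557.487	2247	5124.163
miR-315-5p	345	465.641	254	556.891
miR-316-5p	2143	2971.686	1923	4322.012
miR-317-3p	311250	429211.869	226595	509795.976
miR-375-3p	2744	3957.724	2693	6304.047
miR-927-5p	1167	1603.931	721	1608.971
miR-965-3p	420	554	381	816.976
miR-993-3p	371	531.079	170	398.526
miR-998-3p	242	328.263	221	484.999
miR-2765-5p	401	540.370	553	1210.667
miR-2788-3p	300	427.236	271	632.329
miR-2796-3p	903	1216.746	1172	2550.380
miR-3770-5p	1383	2086.531	1141	2800.141
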