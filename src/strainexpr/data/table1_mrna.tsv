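# Published heritability/correlation table for 67 mRNAs (typed verbatim).
# ci95_consistent is filled only for the four consecutive rows whose printed
# one-tailed CI column is cyclically shifted relative to the ICC formula
# (Mmp1a/Mmp3/Mmp13/Mmp9); ci_shifted flags them.
gene	Vb	Vw	Vt	H2	ci95	ci95_consistent	ci_shifted	p_strain	r_ear	p_ear	r_cart	p_cart
Acan	0.013	0.046	0.059	0.219	0.598		0	0.126	0.414	0.175	0.488	0.139
Adamts4	0.001	0.007	0.008	0.099	0.457		0	0.282	0.018	0.483	-0.169	0.346
Adamts5	0.003	0.007	0.010	0.279	0.661		0	0.078	0.163	0.352	0.110	0.398
Adipoq	0.012	0.021	0.033	0.375	0.750		0	0.022	-0.530	0.121	-0.714	0.066
Apln	-0.001	0.006	0.005	-0.118	0.325		0	0.725	0.148	0.364	0.155	0.359
Atg7	0.016	0.003	0.020	0.824	0.987		0	<0.001	-0.223	0.302	-0.196	0.324
Axin2	0.003	0.008	0.011	0.258	0.639		0	0.077	0.802	0.049	0.814	0.047
Bcl3	0.007	0.011	0.018	0.377	0.751		0	0.030	-0.353	0.210	-0.566	0.107
Becn1	0.002	0.004	0.006	0.356	0.733		0	0.028	-0.127	0.383	-0.033	0.469
Bglap1	0.027	0.016	0.043	0.636	0.924		0	<0.001	-0.127	0.383	-0.033	0.469
Bmp6	0.000	0.003	0.003	-0.133	0.325		0	0.758	-0.195	0.325	-0.114	0.395
Casp3	0.003	0.004	0.008	0.441	0.803		0	0.014	0.712	0.066	0.740	0.060
Ccl3	0.003	0.065	0.068	0.044	0.386		0	0.378	-0.335	0.222	-0.285	0.256
Cdkn1a	-0.004	0.016	0.012	-0.318	0.325		0	0.991	-0.294	0.250	-0.173	0.343
Cdkn2a	0.000	0.009	0.009	0.019	0.352		0	0.419	0.398	0.184	0.383	0.192
Cebpb	0.002	0.015	0.017	0.138	0.505		0	0.222	-0.673	0.075	-0.786	0.051
Chrdl1	0.000	0.006	0.007	0.068	0.417		0	0.321	0.417	0.173	0.385	0.191
Col10a1	0.004	0.080	0.084	0.043	0.384		0	0.380	0.014	0.487	0.218	0.306
Col1a1	0.000	0.009	0.009	-0.044	0.325		0	0.553	-0.342	0.217	-0.208	0.314
Col2a1	0.019	0.044	0.062	0.299	0.680		0	0.065	0.358	0.207	0.417	0.173
Col6a6	-0.001	0.020	0.018	-0.067	0.325		0	0.601	0.380	0.194	0.269	0.267
Comp	0.004	0.042	0.045	0.078	0.430		0	0.317	0.255	0.278	0.317	0.234
Csnk2a1	0.000	0.002	0.002	0.046	0.388		0	0.364	-0.586	0.101	-0.473	0.145
Cxcl12	0.000	0.003	0.004	0.112	0.474		0	0.261	0.574	0.105	0.580	0.103
Ddr2	0.005	0.012	0.017	0.293	0.674		0	0.068	0.124	0.386	0.157	0.357
Epas1	0.001	0.002	0.004	0.375	0.750		0	0.031	-0.067	0.438	-0.063	0.441
Fancc	0.000	0.003	0.003	-0.036	0.325		0	0.541	0.641	0.084	0.689	0.071
Fgf18	0.015	0.023	0.039	0.396	0.767		0	0.024	-0.196	0.324	-0.265	0.270
Fzd2	0.000	0.005	0.004	-0.101	0.325		0	0.687	0.561	0.109	0.643	0.083
Gdf5	0.008	0.024	0.032	0.247	0.628		0	0.102	-0.112	0.397	-0.198	0.322
Igf1	0.017	0.017	0.034	0.505	0.849		0	0.006	-0.184	0.334	-0.215	0.308
Ihh	0.011	0.010	0.022	0.529	0.864		0	0.002	0.325	0.228	0.448	0.157
Il4	0.002	0.005	0.007	0.247	0.628		0	0.102	0.090	0.416	-0.085	0.421
Il6	-0.001	0.009	0.008	-0.087	0.325		0	0.643	0.820	0.046	0.755	0.057
Lef1	0.000	0.009	0.009	-0.003	0.325		0	0.466	0.185	0.333	0.375	0.197
Lep	0.000	0.010	0.010	-0.009	0.325		0	0.481	-0.661	0.078	-0.694	0.070
Map1lc3a	0.001	0.003	0.004	0.251	0.632		0	0.082	-0.770	0.054	-0.636	0.085
Mia1	0.016	0.012	0.028	0.575	0.892		0	0.002	0.407	0.179	0.492	0.137
Mmp13	0.013	0.017	0.030	0.446	0.964	0.807	1	0.013	0.570	0.106	0.562	0.109
Mmp1a	0.000	0.007	0.006	-0.013	0.807	0.325	1	0.489	-0.371	0.199	-0.353	0.210
Mmp3	0.028	0.091	0.119	0.234	0.325	0.614	1	0.113	0.444	0.159	0.294	0.249
Mmp9	0.020	0.007	0.027	0.737	0.614	0.964	1	<0.001	-0.157	0.357	-0.039	0.463
Nampt	0.000	0.002	0.002	-0.114	0.325		0	0.716	0.335	0.222	0.108	0.400
Nfkb1	0.001	0.002	0.002	0.256	0.637		0	0.094	-0.446	0.158	-0.535	0.119
Pcna	0.002	0.007	0.009	0.209	0.587		0	0.119	0.893	0.036	0.925	0.032
Polq	0.008	0.008	0.016	0.477	0.830		0	0.005	0.104	0.404	0.126	0.384
Pthlh	-0.001	0.013	0.012	-0.077	0.325		0	0.634	0.250	0.281	0.424	0.170
Retn	0.000	0.004	0.003	-0.144	0.325		0	0.779	-0.325	0.228	-0.450	0.156
Runx2	0.003	0.004	0.007	0.412	0.780		0	0.020	0.654	0.080	0.714	0.066
Smad1	0.002	0.006	0.008	0.217	0.596		0	0.111	0.411	0.177	0.416	0.174
Smad2	0.000	0.002	0.002	0.131	0.497		0	0.215	0.155	0.359	0.120	0.389
Smad4	0.000	0.002	0.002	0.095	0.452		0	0.272	0.375	0.197	0.449	0.157
Sox5	0.001	0.013	0.014	0.058	0.404		0	0.339	0.635	0.085	0.683	0.073
Sox9	-0.001	0.027	0.026	-0.036	0.325		0	0.536	0.204	0.318	0.271	0.266
Stat3	0.000	0.003	0.003	0.129	0.494		0	0.235	0.044	0.459	-0.152	0.361
Stat6	0.000	0.004	0.004	0.075	0.427		0	0.323	0.362	0.204	0.389	0.189
Tfap2a	0.002	0.007	0.010	0.250	0.631		0	0.099	0.112	0.396	0.075	0.431
Tgfb1	0.002	0.003	0.005	0.437	0.800		0	0.015	-0.416	0.174	-0.466	0.148
Tgfbr1	0.001	0.003	0.003	0.209	0.587		0	0.137	-0.199	0.322	-0.196	0.324
Trp53	0.000	0.003	0.003	0.123	0.487		0	0.226	-0.103	0.404	-0.338	0.220
Ulk1	0.003	0.003	0.006	0.475	0.828		0	0.006	0.643	0.083	0.773	0.054
Vegfa	0.001	0.006	0.007	0.132	0.498		0	0.214	-0.141	0.370	-0.128	0.383
Wisp1	0.008	0.011	0.019	0.433	0.797		0	0.010	0.320	0.232	0.356	0.208
Wnt16	-0.002	0.019	0.016	-0.138	0.325		0	0.743	0.776	0.053	0.868	0.039
Wnt3a	0.000	0.008	0.008	0.059	0.406		0	0.349	0.052	0.451	-0.196	0.324
Xpa	-0.001	0.004	0.003	-0.171	0.325		0	0.832	0.714	0.065	0.526	0.123
Xrcc2	0.006	0.007	0.013	0.493	0.841		0	0.004	0.894	0.035	0.818	0.046
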