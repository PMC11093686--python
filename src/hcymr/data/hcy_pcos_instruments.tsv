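variant_id	chromosome	nearby_gene	effect_allele	beta_exposure	se_exposure	p_exposure	f_statistic	beta_finngen	se_finngen	p_finngen	beta_day	se_day	p_day	beta_tyrmi	se_tyrmi	p_tyrmi
rs1801133	1	MTHFR	A	0.1583	0.007	4.34E-104	511.41	0.1196	0.0536	0.026	0.0085	0.034	0.8	-0.0021	0.0277	0.939
rs2275565	1	MTR	T	-0.0542	0.009	1.96E-10	36.27	0.0670	0.0553	0.226	-0.065	0.037	0.079	0.027	0.0294	0.358
rs7422339	2	CPS1	A	0.0864	0.008	4.58E-27	116.64	NA	NA	NA	0.036	0.035	0.3	0.0414	0.0267	0.121
rs9369898	6	MUT	A	0.0449	0.007	2.17E-10	41.14	-0.0468	0.0462	0.311	-0.058	0.032	0.067	-0.0301	0.0258	0.242
rs7130284	11	NOX4	T	-0.1242	0.013	1.88E-20	91.28	-0.0186	0.0668	0.780	0.015	0.063	0.82	0.0091	0.04	0.820
rs154657	16	DPEP1	A	0.0963	0.007	1.74E-43	189.26	-0.0526	0.0465	0.258	0.049	0.032	0.12	-0.0192	0.0252	0.448
rs234709	21	CBS	T	-0.0718	0.007	3.90E-24	105.21	NA	NA	NA	-0.01	0.032	0.75	0.0012	0.0291	0.968
rs4660306	1	MMACHC	T	0.0435	0.007	2.33E-9	38.62	-0.0496	0.0478	0.299	-0.0053	0.033	0.87	0.026	0.0258	0.314
rs42648	7	GTPB10	A	-0.0395	0.007	1.97E-8	31.84	0.0181	0.0467	0.698	0.032	0.031	0.3	0.0241	0.0263	0.358
rs1801222	10	CUBN	A	0.0453	0.007	8.43E-10	41.88	0.0214	0.0488	0.662	-0.049	0.032	0.13	-0.0184	0.0268	0.492
rs2251468	12	HNF1A	A	-0.0512	0.007	1.28E-12	53.50	-0.0319	0.0464	0.491	-0.062	0.033	0.058	-0.0188	0.0253	0.458
rs838133	19	FUT2	A	0.0422	0.007	7.48E-9	36.34	0.1021	0.0471	0.030	-0.014	0.035	0.69	0.0101	0.0267	0.706
rs12780845	10	CUBN	A	0.0529	0.009	7.8E-10	34.55	-0.0434	0.0523	0.406	0.018	0.033	0.59	-0.0293	0.0275	0.288
rs2851391	21	CBS	T	0.056	0.008	1.7E-12	49.00	NA	NA	NA	-0.041	0.031	0.19	0.0363	0.0288	0.208
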