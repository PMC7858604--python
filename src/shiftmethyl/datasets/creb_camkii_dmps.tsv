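gene	probe_id	sign_at_work	ewas_p	anova_work_p	spearman_r	spearman_p
ACTN2	cg11197458	Hypo	0.020	0.677	-0.270	0.237
ACTN2	cg12297935	Hypo	0.014	0.408	-0.181	0.432
ACTN2	cg23109559	Hypo	0.011	0.499	0.265	0.246
ACTN2	cg23233975	Hypo	0.019	0.355	-0.133	0.566
ACTN2	cg26406150	Hypo	0.019	0.914	0.050	0.831
AKAP9	cg16688376	Hypo	0.046	0.822	-0.083	0.720
CALM1	cg01311654	Hyper	0.042	0.355	0.334	0.138
CALM1	cg04712435	Hypo	0.003	0.834	0.345	0.125
CALM1	cg05077358	Hypo	0.004	0.650	0.408	0.066
CAMK2A	cg03873049	Hypo	0.004	0.592	0.015	0.949
CAMK2A	cg06620397	Hypo	0.015	0.233	-0.318	0.160
CAMK2B	cg18848222	Hypo	0.017	0.602	-0.485	0.026
CAMK2B	cg23997477	Hypo	0.008	0.132	0.149	0.519
CAMK2D	cg13801347	Hypo	0.010	0.915	0.008	0.972
CAMK2D	cg17237111	Hyper	6.399E-05	0.236	0.024	0.917
CAMK2D	cg20391984	Hyper	0.005	0.379	0.077	0.742
CAMK2G	cg02032166	Hypo	0.049	0.921	-0.169	0.463
CAMK2G	cg08797625	Hyper	0.010	0.939	-0.087	0.707
CAMK2G	cg17422824	Hypo	0.021	0.499	0.102	0.660
CREB1	cg05019488	Hypo	0.006	0.765	-0.493	0.023
CREB1	cg14129040	Hypo	0.031	0.290	-0.197	0.391
CREB1	cg15749141	Hyper	0.006	0.342	0.353	0.116
DLG4	cg13729891	Hyper	0.034	0.170	-0.179	0.439
DLG4	cg21218476	Hyper	0.011	0.482	-0.114	0.622
GRIN2A	cg00534626	Hypo	0.001	0.099	-0.032	0.890
GRIN2A	cg01344243	Hypo	0.044	0.204	0.068	0.768
GRIN2A	cg06829391	Hypo	0.009	0.414	0.136	0.558
GRIN2A	cg09461286	Hypo	0.028	0.219	0.191	0.408
GRIN2A	cg16378117	Hypo	0.032	0.942	0.257	0.262
GRIN2B	cg03777288	Hypo	0.042	0.073	-0.085	0.715
GRIN2B	cg14351692	Hypo	0.007	0.694	0.185	0.421
GRIN2B	cg23942984	Hypo	0.018	0.162	-0.083	0.720
GRIN2C	cg09722397	Hyper	0.006	0.363	0.068	0.768
GRIN2C	cg13823003	Hypo	3.076E-06	0.037	-0.622	0.003
GRIN2C	cg18035537	Hyper	0.040	0.147	-0.188	0.414
GRIN2C	cg21997766	Hyper	0.039	0.248	0.121	0.602
GRIN2D	cg08525508	Hypo	0.034	0.078	0.269	0.239
GRIN2D	cg12546181	Hypo	1.217E-05	0.086	0.106	0.647
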