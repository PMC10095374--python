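snp	chr	ea	oa	eaf	beta_exp	se_exp	p_exp	beta_out	se_out	p_out	f
rs10195252	2	C	T	0.4051	-0.0019	0.0003	6.100e-9	0.0101	0.0136	0.460	33.8179
rs10420309	19	G	A	0.4375	-0.0019	0.0003	7.400e-9	0.0202	0.0187	0.280	33.4369
rs10965246	9	C	T	0.1767	-0.0043	0.0004	4.300e-24	0.0408	0.0186	0.028	102.4984
rs11257655	10	T	C	0.2082	0.0027	0.0004	6.500e-12	-0.0202	0.0216	0.350	47.1683
rs11708067	3	G	A	0.2424	-0.0022	0.0004	9.500e-9	0.0202	0.0199	0.310	32.9477
rs1215468	13	G	A	0.2914	-0.0029	0.0004	2.700e-16	-0.0100	0.0340	0.770	66.9935
rs13266634	8	T	C	0.3096	-0.0025	0.0004	3.800e-13	0.0392	0.0183	0.032	52.7446
rs1421085	16	C	T	0.4035	0.0035	0.0003	1.100e-26	-0.0100	0.0233	0.670	114.2529
rs1496653	3	G	A	0.2034	-0.0029	0.0004	3.500e-13	0.0101	0.0418	0.810	52.8812
rs17036160	3	T	C	0.1175	-0.0031	0.0005	4.700e-10	-0.0619	0.0280	0.027	38.7915
rs17513135	1	T	C	0.2275	0.0023	0.0004	3.700e-9	-0.0101	0.0442	0.820	34.7648
rs1800961	20	T	C	0.0310	0.0054	0.0009	9.000e-9	0.0583	0.0465	0.210	33.0454
rs2796441	9	A	G	0.4185	-0.0018	0.0003	2.500e-8	-0.0101	0.0203	0.620	31.0899
rs34744311	10	T	C	0.3773	-0.0028	0.0003	1.600e-17	-0.0202	0.0161	0.210	72.5694
rs34872471	10	C	T	0.2918	0.0086	0.0004	1.099e-127	-0.0488	0.0188	0.009	577.9145
rs459193	5	G	A	0.7466	0.0024	0.0004	1.900e-10	-0.0392	0.0228	0.086	40.5767
rs4686471	3	C	T	0.6101	0.0019	0.0003	1.400e-8	0.0101	0.0228	0.660	32.1655
rs4752792	11	A	G	0.5445	0.0021	0.0003	1.100e-10	0.0296	0.0236	0.210	41.5855
rs4932264	15	C	T	0.7296	-0.0022	0.0004	1.200e-9	-0.0198	0.0240	0.410	36.9493
rs67232546	11	T	C	0.2125	0.0023	0.0004	1.100e-8	-0.0202	0.0212	0.340	32.6216
rs6769511	3	C	T	0.3158	0.0032	0.0003	6.001e-20	-0.0198	0.0216	0.360	83.6027
rs7177055	15	A	G	0.7175	0.0022	0.0004	3.700e-10	-0.0101	0.0252	0.690	39.2887
rs72802357	16	T	C	0.0781	-0.0040	0.0006	2.500e-11	0.0677	0.0283	0.017	44.5496
rs73188924	22	A	C	0.2248	0.0022	0.0004	2.400e-8	-0.0202	0.0322	0.530	31.1092
rs7482891	11	G	A	0.6221	-0.0022	0.0003	7.800e-11	0.0101	0.0252	0.690	42.3038
rs7756992	6	G	A	0.2664	0.0032	0.0004	2.200e-18	0.0101	0.0122	0.410	76.4924
rs780093	2	C	T	0.6152	0.0021	0.0003	5.100e-10	0.0101	0.0133	0.450	38.6220
rs849142	7	C	T	0.5051	-0.0024	0.0003	1.300e-13	0.0202	0.0179	0.260	54.9143
rs8756	12	A	C	0.5176	0.0019	0.0003	5.700e-9	-0.0305	0.0164	0.063	33.9234
rs947791	11	A	G	0.2176	0.0023	0.0004	5.500e-9	-0.0202	0.0230	0.380	34.0158
rs987237	6	G	A	0.1796	0.0024	0.0004	8.400e-9	0.0305	0.0300	0.310	33.1730
rs9957264	18	A	C	0.1665	-0.0026	0.0004	1.600e-9	0.0198	0.0191	0.300	36.4231
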