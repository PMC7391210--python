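miRNA	case_readcount	control_readcount	log2FoldChange	pvalue	direction
hsa-miR-1246	392.891	122.970	1.400	0.000	up
hsa-miR-27a-5p	299.030	122.568	1.127	0.001	up
hsa-miR-1291	37.767	10.102	1.398	0.001	up
hsa-miR-574-5p	61.804	25.432	1.109	0.002	up
hsa-miR-196a-5p	235.302	48.010	1.443	0.003	up
hsa-miR-365a-5p	13.963	2.770	1.423	0.003	up
hsa-miR-7704	18.263	4.184	1.354	0.003	up
hsa-miR-522-3p	15.708	2.740	1.357	0.006	up
hsa-miR-767-5p	2.409	0.000	1.302	0.006	up
hsa-miR-4677-5p	2.954	0.585	1.271	0.010	up
hsa-miR-452-5p	101.282	55.955	0.768	0.012	up
hsa-miR-556-5p	12.751	4.314	1.094	0.015	up
hsa-miR-105-5p	11.412	1.996	1.204	0.015	up
hsa-miR-548ah-3p	27.558	12.547	0.909	0.017	up
hsa-miR-548p	27.558	12.745	0.892	0.018	up
hsa-miR-487b-5p	2.360	0.099	1.122	0.019	up
hsa-miR-203a-3p	40.489	21.240	0.783	0.020	up
hsa-miR-203b-5p	40.489	21.240	0.783	0.020	up
hsa-miR-3128	2.148	0.487	1.099	0.027	up
hsa-miR-551a	6.673	2.561	1.020	0.027	up
hsa-miR-1-3p	1564.803	692.038	0.911	0.028	up
hsa-miR-552-3p	5.304	1.311	1.059	0.033	up
hsa-miR-4654	3.021	0.446	1.030	0.036	up
hsa-miR-1185-2-3p	4.428	1.506	1.005	0.039	up
hsa-miR-2277-5p	4.042	1.080	0.987	0.040	up
hsa-miR-7-5p	4353.305	2404.923	0.727	0.041	up
hsa-miR-3529-3p	4290.922	2395.239	0.715	0.043	up
hsa-miR-941	994.324	478.947	0.822	0.045	up
hsa-miR-125b-1-3p	23.944	9.010	0.940	0.046	up
hsa-miR-24-3p	17884.990	12406.933	0.492	0.050	up
novel_259	2.369	0.198	0.938	0.050	up
novel_428	2.369	0.198	0.938	0.050	up
hsa-miR-141-5p	0.966	0.000	0.849	0.050	up
hsa-miR-223-5p	8001.591	4445.220	0.713	0.050	up
hsa-miR-150-5p	437.928	1442.383	-1.450	0.000	down
hsa-miR-4685-3p	4.820	17.512	-1.516	0.000	down
hsa-miR-3173-5p	7.688	19.653	-1.226	0.001	down
hsa-miR-484	1324.464	2478.547	-0.838	0.001	down
hsa-miR-204-5p	18.582	53.285	-1.262	0.001	down
hsa-miR-451a	882525.102	1304912.611	-0.546	0.002	down
hsa-miR-4745-5p	0.072	2.796	-1.526	0.002	down
hsa-miR-1306-5p	4.433	14.641	-1.260	0.002	down
hsa-miR-6815-5p	5.666	15.268	-1.144	0.003	down
hsa-miR-4732-3p	78.048	182.434	-1.039	0.003	down
hsa-miR-92a-3p	27155.615	58429.371	-0.962	0.004	down
hsa-miR-501-3p	697.870	1311.606	-0.821	0.005	down
hsa-miR-6511b-3p	1.098	5.724	-1.284	0.008	down
hsa-miR-486-3p	135096.262	240658.136	-0.755	0.009	down
hsa-miR-483-3p	11.806	32.370	-1.126	0.010	down
hsa-miR-486-5p	137121.872	241531.605	-0.742	0.010	down
hsa-miR-6850-5p	0.990	4.660	-1.199	0.014	down
hsa-miR-6803-3p	0.450	4.295	-1.181	0.017	down
hsa-miR-6750-5p	2.714	9.667	-1.143	0.017	down
hsa-miR-1180-3p	481.900	867.740	-0.751	0.019	down
hsa-miR-550a-3p	1.732	6.826	-1.146	0.021	down
hsa-miR-550b-2-5p	1.732	6.826	-1.146	0.021	down
hsa-miR-150-3p	74.077	114.320	-0.584	0.021	down
hsa-miR-1976	4.705	12.108	-1.008	0.026	down
hsa-miR-4732-5p	174.145	318.996	-0.755	0.027	down
hsa-miR-1229-3p	0.424	3.350	-1.087	0.028	down
hsa-miR-3605-3p	9.607	24.837	-0.981	0.029	down
hsa-miR-4753-3p	0.436	2.708	-1.060	0.032	down
hsa-miR-4742-3p	6.878	17.211	-0.920	0.034	down
hsa-miR-320a	52468.459	97066.421	-0.753	0.035	down
hsa-miR-592	0.000	1.103	-0.914	0.037	down
hsa-miR-125a-5p	1558.052	3170.278	-0.819	0.039	down
hsa-miR-146b-3p	18.873	34.714	-0.758	0.040	down
hsa-miR-320b	3442.955	6415.482	-0.752	0.040	down
novel_521	0.177	1.756	-0.964	0.041	down
hsa-miR-191-5p	11410.077	17378.885	-0.556	0.043	down
hsa-miR-1228-5p	10.059	20.298	-0.788	0.044	down
hsa-miR-1285-3p	87.723	144.269	-0.629	0.045	down
hsa-miR-6833-3p	0.249	1.981	-0.968	0.046	down
novel_759	0.000	1.378	-0.850	0.048	down
hsa-miR-3918	0.567	2.484	-0.983	0.048	down
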