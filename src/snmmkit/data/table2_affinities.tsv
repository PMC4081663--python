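sequence	EMSA	PC	SNMM	PWMSA	Match	PBM
GGGGATTCCC	2.704	0.992	0.987	1	1	8.230
GGGGAATCCC	2.614	0.977	0.903	0.923	0.925	7.639
GGGGCTTCCC	2.444	0.981	0.972	0.979	0.923	5.197
GGGGTTCCCC	2.356	0.957	0.901	0.977	0.915	5.970
GGGGGATTCC	2.336	0.856	0.872	0.815	0.766	6.572
GGGAATTTCC	2.328	0.641	0.971	0.967	0.845	5.870
GGGGTTTTCC	2.322	0.953	0.964	0.958	0.846	5.964
GGGAAATTCC	2.258	0.633	0.888	0.885	0.77	6.192
GGGGACTTCC	2.155	0.762	0.856	0.904	0.848	4.773
GGGATCTCCC	2.057	0.813	0.895	0.881	0.771	4.350
GGGGAGTCCC	1.991	0.934	0.898	0.99	0.94	4.831
GGGGGCTCCC	1.929	0.684	0.877	0.834	0.843	3.640
GGGGGCTTCC	1.826	0.68	0.851	0.815	0.766	4.460
GGGATACCCC	1.799	0.918	0.828	0.881	0.763	2.892
GGGGAGCCCC	1.756	0.926	0.81	0.99	0.932	3.613
GGGGACCCCC	1.748	0.945	0.793	0.929	0.917	3.675
GGGATGTCCC	1.732	0.793	0.912	0.949	0.786	3.914
GGGGCTCCCC	1.69	0.922	0.883	0.979	0.915	3.613
GGGAACTTCC	1.663	0.492	0.866	0.885	0.77	4.036
GGAATACCCC	1.653	0.875	0.76	0.754	0.63	3.370
GGGATATCCC	1.623	0.828	0.917	0.881	0.771	4.179
GGGGTATCCC	1.602	0.914	0.907	0.901	0.848	2.892
GGGGCACCCC	1.491	0.77	0.8	0.902	0.84	2.010
GGGGCCCCCC	1.477	0.695	0.778	0.902	0.84	2.917
GGGAGGCCCC	1.447	0.75	0.814	0.881	0.772	2.420
GGGACTCTCC	1.431	0.273	0.867	0.941	0.76	3.406
GGGGGCCCCC	1.431	0.664	0.788	0.833	0.835
GGAGAACCCC	1.415	0.621	0.747	0.796	0.784	2.214
GGGGGGCTCC	1.301	0.391	0.779	0.881	0.772	3.170
GGAGGGTTCC	0.954	0.031	0.8	0.755	0.648
GGAAGGCCCC	0.903	0.516	0.746	0.755	0.639	1.856
GGAAATTTCC	0.778	0.184	0.903	0.835	0.712	3.278
GGAACGCCCC	0.778	0.59	0.737	0.823	0.645	2.326
GGAGCGCCCC	0.778	0.332	0.727	0.843	0.722
GGGAGCTCCC	0.699	0.637	0.887	0.815	0.766	3.079
GGGGTACTCC	0.699	0.484	0.792	0.881	0.763	2.131
GGGGTGCTCC	0.699	0.422	0.787	0.948	0.777
GGAGGATCCC	0.602	0.16	0.83	0.707	0.71
GGAACGTCCC	0.477	0.316	0.826	0.824	0.653	2.453
GGAAGCTTCC	0.477	0.004	0.793	0.669	0.556
GGAATTCTCC	0.477	0.199	0.817	0.812	0.627	1.062
GGGAGTCTCC	0.477	0.301	0.877	0.872	0.755	2.378
GGGATCCTCC	0.477	0.156	0.781	0.862	0.685
GGAACCTCCC	0.301	0.383	0.809	0.757	0.638	0.950
GGAACTTTCC	0.301	0.039	0.888	0.814	0.635	1.332
GGAAGGCTCC	0.301	0.012	0.721	0.735	0.562
GGAAGTTTCC	0.301	0.09	0.898	0.746	0.63	0.946
GGAGGCTCCC	0.301	0.121	0.809	0.707	0.71
GGGAGACTCC	0.301	0.258	0.793	0.795	0.68	1.960
GGAATATTCC	0	0.008	0.823	0.735	0.561	1.495
GGAGACCTCC	0	0.078	0.699	0.777	0.706
GGAGGCCTCC	0	0	0.694	0.687	0.624
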