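coverage	quantizer	tp	fp	fn	rec	prec	f1
90	Original	3317116	10041	10376	0.9969	0.9970	0.9969
90	Q8	3317064	10071	10428	0.9969	0.9970	0.9969
90	Q4	3316599	9994	10893	0.9967	0.9970	0.9969
90	Q2	3315132	10023	12360	0.9963	0.9970	0.9966
90	F10	3310775	9522	16717	0.9950	0.9971	0.9961
90	Q2Q8ctx	3315867	10121	11625	0.9965	0.9970	0.9967
50	Original	3314614	13842	12878	0.9961	0.9958	0.9960
50	Q8	3314564	14160	12928	0.9961	0.9957	0.9959
50	Q4	3314059	14488	13433	0.9960	0.9956	0.9958
50	Q2	3312857	14693	14635	0.9956	0.9956	0.9956
50	F10	3310166	14337	17326	0.9948	0.9957	0.9952
50	Q2Q8ctx	3313530	14780	13962	0.9958	0.9956	0.9957
40	Original	3312510	20159	14982	0.9955	0.9940	0.9947
40	Q8	3312554	20778	14938	0.9955	0.9938	0.9946
40	Q4	3312056	21237	15436	0.9954	0.9936	0.9945
40	Q2	3310979	21442	16513	0.9950	0.9936	0.9943
40	F10	3308694	21260	18798	0.9944	0.9936	0.9940
40	Q2Q8ctx	3311573	21820	15919	0.9952	0.9935	0.9943
30	Original	3307863	60007	19629	0.9941	0.9822	0.9881
30	Q8	3307922	63022	19570	0.9941	0.9813	0.9877
30	Q4	3307467	62382	20025	0.9940	0.9815	0.9877
30	Q2	3306457	61682	21035	0.9937	0.9817	0.9876
30	F10	3303993	61874	23499	0.9929	0.9816	0.9872
30	Q2Q8ctx	3306928	62256	20564	0.9938	0.9815	0.9876
20	Original	3285668	466868	41824	0.9874	0.8756	0.9282
20	Q8	3285516	494441	41976	0.9874	0.8692	0.9245
20	Q4	3284787	464226	42705	0.9872	0.8762	0.9284
20	Q2	3283171	432505	44321	0.9867	0.8836	0.9323
20	F10	3277795	442196	49697	0.9851	0.8812	0.9302
20	Q2Q8ctx	3283622	442501	43870	0.9868	0.8813	0.9311
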