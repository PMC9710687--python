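coverage	quantizer	tp	fp	fn	rec	prec	f1
90	Original	303517	29403	200983	0.6016	0.9136	0.7255
90	Q8	303713	29607	200787	0.6020	0.9131	0.7256
90	Q4	301600	30180	202900	0.5978	0.9110	0.7219
90	Q2	296238	30968	208262	0.5872	0.9074	0.7130
90	F10	289838	28569	214662	0.5745	0.9123	0.7050
90	Q2Q8ctx	304333	37142	200167	0.6032	0.8935	0.7202
50	Original	287895	43665	216605	0.5707	0.8709	0.6895
50	Q8	287890	44025	216610	0.5706	0.8699	0.6892
50	Q4	286319	43663	218181	0.5675	0.8703	0.6870
50	Q2	283147	44307	221353	0.5612	0.8673	0.6815
50	F10	279418	42311	225082	0.5539	0.8711	0.6772
50	Q2Q8ctx	289053	51537	215447	0.5729	0.8515	0.6850
40	Original	278841	51239	225659	0.5527	0.8476	0.6691
40	Q8	278920	51314	225580	0.5529	0.8475	0.6692
40	Q4	277724	51171	226776	0.5505	0.8473	0.6674
40	Q2	275492	51998	229008	0.5461	0.8442	0.6632
40	F10	272761	50237	231739	0.5407	0.8474	0.6601
40	Q2Q8ctx	280046	59427	224454	0.5551	0.8281	0.6646
30	Original	265283	63876	239217	0.5258	0.8092	0.6374
30	Q8	265193	64151	239307	0.5257	0.8085	0.6371
30	Q4	264442	64213	240058	0.5242	0.8079	0.6358
30	Q2	263047	65037	241453	0.5214	0.8051	0.6329
30	F10	260681	63727	243819	0.5167	0.8069	0.6300
30	Q2Q8ctx	266429	72561	238071	0.5281	0.7894	0.6329
20	Original	239522	96040	264978	0.4748	0.7177	0.5715
20	Q8	239532	96766	264968	0.4748	0.7162	0.5710
20	Q4	238938	95403	265562	0.4736	0.7185	0.5709
20	Q2	237475	94862	267025	0.4707	0.7185	0.5688
20	F10	235169	92383	269332	0.4661	0.7219	0.5665
20	Q2Q8ctx	239968	102876	264532	0.4757	0.7039	0.5677
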