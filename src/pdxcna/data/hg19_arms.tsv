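chromosome	start	end	arm
1	0	121535434	p
1	124535434	249250621	q
2	0	92326171	p
2	95326171	243199373	q
3	0	90504854	p
3	93504854	198022430	q
4	0	49660117	p
4	52660117	191154276	q
5	0	46405641	p
5	49405641	180915260	q
6	0	58830166	p
6	61830166	171115067	q
7	0	58054331	p
7	61054331	159138663	q
8	0	43838887	p
8	46838887	146364022	q
9	0	47367679	p
9	50367679	141213431	q
10	0	39254935	p
10	42254935	135534747	q
11	0	51644205	p
11	54644205	135006516	q
12	0	34856694	p
12	37856694	133851895	q
13	0	16000000	p
13	19000000	115169878	q
14	0	16000000	p
14	19000000	107349540	q
15	0	17000000	p
15	20000000	102531392	q
16	0	35335801	p
16	38335801	90354753	q
17	0	22263006	p
17	25263006	81195210	q
18	0	15460898	p
18	18460898	78077248	q
19	0	24681782	p
19	27681782	59128983	q
20	0	26369569	p
20	29369569	63025520	q
21	0	11288129	p
21	14288129	48129895	q
22	0	13000000	p
22	16000000	51304566	q
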