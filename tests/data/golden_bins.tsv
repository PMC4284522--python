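#bin_id	source_name	start	end	n_rf	length_bp
0	chr01	0	3432	8	3432
0	chr01	3432	6865	9	3433
1	chr01	6865	10298	8	3433
1	chr01	10298	13731	9	3433
2	chr02	0	12125	30	12125
2	chr02	12125	24251	31	12126
3	chr02	24251	36377	30	12126
3	chr02	36377	48503	31	12126
4	chr03	0	4721	12	4721
4	chr03	4721	9442	12	4721
5	chr03	9442	14163	12	4721
5	chr03	14163	18885	12	4722
6	chr04	0	15228	38	15228
6	chr04	15228	30457	38	15229
7	chr04	30457	45685	38	15228
7	chr04	45685	60914	38	15229
8	chr04	60914	76143	38	15229
8	chr04	76143	91373	38	15230
9	chr05	0	8602	22	8602
9	chr05	8602	17204	21	8602
10	chr05	17204	25806	22	8602
10	chr05	25806	34408	21	8602
11	chr06	0	4028	10	4028
11	chr06	4028	8057	10	4029
12	chr06	8057	12085	10	4028
12	chr06	12085	16114	10	4029
13	chr07	0	16267	40	16267
13	chr07	16267	32535	41	16268
14	chr07	32535	48802	40	16267
14	chr07	48802	65070	41	16268
15	chr08	0	8389	21	8389
15	chr08	8389	16779	21	8390
16	chr08	16779	25169	21	8390
16	chr08	25169	33559	21	8390
17	chr09	0	6559	16	6559
17	chr09	6559	13118	17	6559
18	chr09	13118	19677	16	6559
18	chr09	19677	26237	17	6560
19	chr10	0	11120	28	11120
19	chr10	11120	22240	28	11120
20	chr10	22240	33360	28	11120
20	chr10	33360	44481	28	11121
21	chr11	0	9943	25	9943
21	chr11	9943	19886	25	9943
22	chr11	19886	29829	25	9943
22	chr11	29829	39773	25	9944
23	chr12	0	16077	40	16077
23	chr12	16077	32154	40	16077
24	chr12	32154	48231	40	16077
24	chr12	48231	64308	40	16077
25	chr13	0	13784	34	13784
25	chr13	13784	27569	35	13785
26	chr13	27569	41353	34	13784
26	chr13	41353	55138	35	13785
27	chr14	0	11695	29	11695
27	chr14	11695	23391	29	11696
28	chr14	23391	35086	29	11695
28	chr14	35086	46782	29	11696
29	chr15	0	16272	40	16272
29	chr15	16272	32545	41	16273
30	chr15	32545	48818	40	16273
30	chr15	48818	65091	41	16273
31	chr16	0	14137	36	14137
31	chr16	14137	28274	35	14137
32	chr16	28274	42411	36	14137
32	chr16	42411	56548	35	14137
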