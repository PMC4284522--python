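#scaffold	rank	bin_id	orientation	copy_index
chr01	0	0	+	0
chr01	1	1	+	0
chr02	0	2	+	0
chr02	1	3	+	0
chr03	0	4	+	0
chr03	1	5	+	0
chr04	0	6	+	0
chr04	1	7	+	0
chr04	2	8	+	0
chr05	0	9	+	0
chr05	1	10	+	0
chr06	0	11	+	0
chr06	1	12	+	0
chr07	0	13	+	0
chr07	1	14	+	0
chr08	0	15	+	0
chr08	1	16	+	0
chr09	0	17	+	0
chr09	1	18	+	0
chr10	0	19	+	0
chr10	1	20	+	0
chr11	0	21	+	0
chr11	1	22	+	0
chr12	0	23	+	0
chr12	1	24	+	0
chr13	0	25	+	0
chr13	1	26	+	0
chr14	0	27	+	0
chr14	1	28	+	0
chr15	0	29	+	0
chr15	1	30	+	0
chr16	0	31	+	0
chr16	1	32	+	0
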