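cluster_type	subtype	signature	length_printed	Alphaproteobacteria	Firmicutes	Archaea	Bacteria_lit	Eukarya
2Fe-2S	1	CX5CX2CX36C	47	296	0	0	2	64
2Fe-2S	2	CX5CX2CX37C	48	81	1	0	4	22
2Fe-2S	3	CX4CX2CX29C	39	11	1	7	11	55
2Fe-2S	4	CX5CX2CX35C	46	12	3	0	2	0
2Fe-2S	5	CX5CX2CX38C	49	12	1	0	0	0
2Fe-2S	6	CX4CX2CX34C	44	11	11	7	1	0
2Fe-2S	7	CX4CX2CX51C	61	8	0	0	1	0
2Fe-2S	8	CX4CX2CX31C	41	7	6	1	1	0
2Fe-2S	9	CX4CX2CX33C	43	2	3	19	0	2
2Fe-2S	10	CX5CX2CX39C	50	2	0	0	1	0
2Fe-2S	11	CX4CX2CX35C	46	1	0	0	0	0
2Fe-2S	12	CX4CX2CX25C	35	1	0	0	0	0
2Fe-2S	13	CX7CX34CX3C	48	1	0	0	0	0
2Fe-2S	14	CX4CX29C	36	1	0	0	0	0
2Fe-2S	15	CX7CX29C	39	1	0	0	0	0
2Fe-2S	16	CX7CX35C	45	1	0	0	0	0
2Fe-2S	17	CX5CX2CX33C	44	1	0	0	0	0
2Fe-2S	18	CX5CX2CX34C	45	2	20	2	1	1
2Fe-2S	19	CX5CX2CX35C	46	1	0	0	0	0
2Fe-2S	20	CX5CX2CX32C	43	0	44	0	1	5
2Fe-2S	21	CX4CX31CX3C	42	0	5	0	0	0
2Fe-2S	22	CX2CX41CX3C	50	0	2	0	0	0
2Fe-2S	23	CX7CX38CX3C	52	0	0	0	1	0
2Fe-2S	24	CX4CX2CX30C	40	0	0	70	0	1
2Fe-2S	25	CX5CX2CX30C	41	0	0	0	0	1
2Fe-2S	26	CX12CX30CX3C	49	21	0	0	0	0
2Fe-2S	27	CX12CX31CX3C	50	4	0	0	0	0
2Fe-2S	28	CX8CX44CX3C	59	3	0	0	0	0
2Fe-2S	29	CX8CX33CX3C	48	3	0	0	0	0
2Fe-2S	30	CX8CX32CX3C	47	2	0	0	0	0
2Fe-2S	31	CX4CX36CX3C	47	1	0	1	0	0
2Fe-2S	32	CX8CX38CX3C	53	1	0	0	0	0
2Fe-2S	33	CX8CX39CX3C	54	1	0	0	0	0
2Fe-2S	34	CX9CX33CX3C	49	1	0	0	0	0
2Fe-2S	35	CX12CX33CX3C	52	1	0	0	0	0
2Fe-2S	36	CX3CX1CX38C	46	0	0	0	1	0
2Fe-2S	37	CX12CX32CX3C	51	0	0	0	1	0
2Fe-2S	38	CX4CX2CX28C	38	0	0	40	0	3
2Fe-2S	39	CX4CX2CX46C	56	0	0	2	0	0
2Fe-2S	40	CX4CX2CX49C	59	0	0	3	0	0
2Fe-2S	41	CX4CX2CX45C	55	0	0	2	0	0
2Fe-2S	42	CX4CX2CX65C	75	0	0	1	0	0
2Fe-2S	43	CX4CX2CX50C	60	0	0	2	0	0
2Fe-2S	44	CX4CX2CX47C	57	0	0	2	0	0
2Fe-2S	45	CX4CX2CX48C	58	0	0	1	0	0
2Fe-2S	46	CX5CX2CX52C	63	0	0	2	0	0
2Fe-2S	47	CX5CX2CX31C	42	0	0	1	0	0
2Fe-2S	48	CX5CX2CX28C	39	0	0	2	0	0
2Fe-2S	49	CX5CX2CX27C	38	0	0	10	0	0
2Fe-2S	50	CX5CX2CX82C	93	0	0	2	0	0
2Fe-2S	51	CX5CX2CX29C	40	0	0	1	0	0
2Fe-2S	52	CX4CX2CX32C	42	0	0	1	0	0
2Fe-2S	53	CX5CX2CX42C	53	0	0	0	0	1
2Fe-2S	54	CX4CX2CX22C	32	0	0	0	0	2
2Fe-2S	55	CX4CX2CX29C	39	0	0	2	0	0
3Fe-4S	1	CX5CX38CP	47	26	0	2	7	0
3Fe-4S	2	CX5CX37CP	46	16	0	0	13	0
3Fe-4S	3	CX5CX36CP	45	14	0	0	2	0
3Fe-4S	4	CX5CX40CP	49	3	0	0	0	0
3Fe-4S	5	CX5CX36CP	45	1	0	0	0	0
3Fe-4S	6	CX5CX35CP	44	0	0	0	5	0
3Fe-4S	7	CX5CX49CP	58	0	0	0	2	0
4Fe-4S	1	CX5CX3CX33CP	46	2	0	0	0	0
4Fe-4S	2	CX2CX2CX43CP	52	0	107	0	0	0
4Fe-4S	3	CX2CX2CX45CP	54	0	24	0	1	0
4Fe-4S	4	CX2CX2CX37CP	46	0	6	0	0	0
4Fe-4S	5	CX2CX2CX44CP	53	0	2	0	0	0
4Fe-4S	6	CX2CX2CX39CP	48	0	1	0	0	0
4Fe-4S	7	CX2CX2CX36CP	45	0	0	0	2	0
4Fe-4S	8	CX2CX2CX34CP	43	0	0	0	1	0
4Fe-4S	9	CX2CX2CX38CP	47	0	0	1	0	1
4Fe-4S	10	CX5CX3CX32CP	45	0	0	1	0	0
4Fe-4S	11	CX5CX3CX30CP	43	0	0	12	0	0
4Fe-4S	12	CX5CX3CX31CP	44	0	0	2	0	0
7Fe-8S	1	CX7CX3CPX17CX2CX2CX3CP	43	6	32	0	13	0
7Fe-8S	2	CX5CX3CPX40CX2CX2CX3CP	64	4	0	0	0	0
7Fe-8S	3	CX5CX3CPX20CX2CX2CX3CP	44	1	0	0	0	0
7Fe-8S	4	CX10CX3CPX22CX2CX2CX3CP	51	1	0	0	0	0
7Fe-8S	5	CX5CX3CPX26CX2CX2CX3CP	50	0	0	1	0	0
7Fe-8S	6	CX5CX3CPX24CX2CX2CX3CP	48	0	0	0	1	1
7Fe-8S	7	CX10CX3CPX17CX2CX2CX3CP	46	0	0	0	1	0
7Fe-8S	8	CX5CX3CPX22CX2CX2CX3CP	46	0	0	9	0	0
7Fe-8S	9	CX5CX3CPX18CX2CX2CX3C	42	0	0	1	0	0
7Fe-8S	10	CX3CX3CPX22CX2CX2CX3CP	44	0	0	2	0	0
2[4Fe-4S]	1	CX2CX4CX3CX18CX2CX2CX3C	42	267	0	0	0	0
2[4Fe-4S]	2	CX2CX2CX3CX18CX2CX8CX3C	46	90	0	0	4	0
2[4Fe-4S]	3	CX2CX2CX3CX20CX2CX2CX3C	42	33	2	52	1	0
2[4Fe-4S]	4	CX7CX2CX3CX23CX2CX2CX3C	50	5	0	0	0	0
2[4Fe-4S]	5	CX2CX2CX3CX42CX2CX2CX3C	64	3	0	0	0	0
2[4Fe-4S]	6	CX2CX2CX3CX18CX2CX7CX3C	45	2	0	0	0	0
2[4Fe-4S]	7	CX2CX2CX3CX18CX2CX6CX3C	44	2	0	0	0	0
2[4Fe-4S]	8	CX2CX2CX3CX24CX2CX2CX3C	46	2	0	2	0	0
2[4Fe-4S]	9	CX2CX2CX3CX18CX2CX2CX3C	40	1	6	78	3	1
2[4Fe-4S]	10	CX2CX2CX3CX21CX2CX2CX3C	43	6	0	2	0	0
2[4Fe-4S]	11	CX2CX2CX3CX18CX3CX2CX3C	42	0	0	2	0	0
2[4Fe-4S]	12	CX2CX2CX3CX28CX2CX2CX3C	50	132	0	1	0	2
2[4Fe-4S]	13	CX2CX2CX3CX27CX2CX2CX3C	49	2	0	0	0	0
2[4Fe-4S]	14	CX5CX2CX3CX20CX2CX2CX3C	45	21	0	0	0	0
2[4Fe-4S]	15	CX2CX2CX3CX19CX2CX2CX3C	41	1	4	58	0	0
2[4Fe-4S]	16	CX2CX2CX3CX40CX2CX2CX3C	50	1	0	0	0	0
2[4Fe-4S]	17	CX2CX2CX3CX29CX2CX2CX3C	51	144	0	0	0	2
2[4Fe-4S]	18	CX4CX2CX3CX18CX2CX2CX3C	42	0	0	1	1	0
2[4Fe-4S]	19	CX3CX2CX3CX20CX2CX2CX3C	43	0	0	0	2	0
2[4Fe-4S]	20	CX2CX2CX3CX17CX2CX2CX3C	39	0	0	24	1	0
2[4Fe-4S]	21	CX3CX3CX3CX37CX1CX3CX3C	61	0	0	0	1	0
2[4Fe-4S]	22	CX2CX2CX3CX26CX2CX2CX3C	48	0	0	0	0	6
2[4Fe-4S]	23	CX2CX2CX3CX30CX2CX2CX3C	52	0	0	0	0	1
2[4Fe-4S]	24	CX2CX2CX3CX33CX2CX2CX3C	55	0	0	22	0	0
2[4Fe-4S]	25	CX2CX2CX3CX32CX2CX2CX3C	54	0	0	23	0	0
2[4Fe-4S]	26	CX2CX2CX3CX23CX2CX2CX3C	45	0	0	2	0	0
2[4Fe-4S]	27	CX2CX2CX3CX34CX2CX2CX3C	56	0	0	1	0	0
2[4Fe-4S]	28	CX2CX2CX3CX14CX2CX2CX3C	36	0	0	2	0	0
2[4Fe-4S]	29	CX2CX2CX3CX22CX2CX2CX3C	44	0	0	2	0	0
2[4Fe-4S]	30	CX2CX2CX2CX38CX2CX2CX3C	59	0	0	1	0	0
2[4Fe-4S]	31	CX4CX2CX3CX19CX2CX2CX3C	43	0	0	24	0	0
2[4Fe-4S]	32	CX5CX2CX3CX19CX2CX2CX3C	44	0	0	3	0	0
2[4Fe-4S]	33	CX2CX2CX3CX16CX2CX2CX3C	38	0	0	16	0	0
2[4Fe-4S]Alv	1	CX2CX2CX3CX18CX2CX8CX3CX3C	50	10	0	0	5	0
2[4Fe-4S]Alv	2	CX2CX2CX3CX39CX2CX2CX3CX3C	65	9	0	0	0	0
2[4Fe-4S]Alv	3	CX2CX2CX3CX43CX2CX2CX3CX3C	69	5	0	0	1	0
2[4Fe-4S]Alv	4	CX2CX2CX3CX42CX2CX2CX3CX3C	68	1	0	0	0	0
2[4Fe-4S]Alv	5	CX2CX2CX3CX40CX2CX2CX3CX3C	66	2	0	0	0	0
2[4Fe-4S]Alv	6	CX2CX2CX3CX38CX2CX2CX3CX3C	64	1	0	0	0	0
2[4Fe-4S]Alv	7	CX2CX2CX3CX46CX2CX2CX3CX3C	72	2	0	0	0	0
2[4Fe-4S]Alv	8	CX2CX2CX3CX44CX2CX2CX3CX3C	70	1	0	0	0	0
2[4Fe-4S]Alv	9	CX2CX2CX3CX30CX2CX2CX3CX3C	56	0	0	2	0	0
2[4Fe-4S]Alv	10	CX2CX2CX3CX19CX2CX2CX3CX3C	45	0	0	8	0	0
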