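sample	fov	n_channels	condition	total_reads	nuc_reads	nuc_bp	mt_reads	mt_bp	loaded_volume_ul	pooled_volume_ul
CA1	1100	1	spiking	4559011	57946	1728020	3	107	.	.
CA1	1100	1	80C	787255	29837	896617	11	365	4	4
CA1	1100	1	95C	35055	1020	27242	0	0	2	6
CA2	1100	1	spiking	4888026	54266	1599775	3	90	.	.
CA2	1100	1	80C	730418	55546	1717054	12	385	4	4
CA2	1100	1	95C	51550	1231	33023	0	0	2	6
TP1	110	1	80C_phosphatase	1980210	85738	2885229	53	1845	.	.
TP1	110	1	80C	234094	28797	998007	8	255	.	.
TP1	110	1	95C	228871	12573	438111	5	162	.	.
TP1RE	110	1	80C_phosphatase	1607848	161284	5597277	99	3378	.	.
TP1RE	550	8	80C_phosphatase	16290720	1480012	46444135	935	29637	.	.
TP1RE	110	1	80C	214070	48304	1718507	29	991	.	.
TP1RE	110	1	95C	356586	51052	1798348	31	1169	.	.
TP2	110	1	80C_phosphatase	2088705	177944	6147860	50	1713	.	.
TP2	110	1	80C	216159	53463	1879011	16	560	.	.
TP2	110	1	95C	354155	62259	2170975	15	516	.	.
TP2RE	110	1	80C_phosphatase	233613	32045	1094783	10	318	.	.
TP2RE	110	1	80C	213958	59530	2072120	26	928	.	.
TP2RE	110	1	95C	247784	55848	1939018	22	781	.	.
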