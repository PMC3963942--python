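id	forward_seq	reverse_seq	target_start	target_end	printed_size_bp
DM#1	AGCACCCTATGTCGCAGTATC	GGTGATGTGAGCCCGTCTAAAC	108	638	531
DM#2	CCAACCAAACCCCAAAGAC	GGGAGGGGGTGATCTAAAAC	548	964	417
DM#3	GCCCCGCCCCAGGGTTGGTCAATTTCGTGCC	GAGCAAGAGGTGGTGAGGTTG	871	1250	390
DM#4	CCTGGCGGTGCTTCATATCC	GCTACACTCTGGTTCGTCCAAG	1172	1612	441
DM#5	GCCCGTCACCCTCCTCAAG	ACGGGTGTGCTCTTTTAGCTG	1485	1950	466
DM#6	GGAGAGCCAAAGCTAAGACCC	GTGTTGGGTTGACAGTGAGGG	1883	2433	551
DM#7	GCAGCCACCAATTAAGAAAGCG	TCTCGTCTTGCTGTGTCATGC	2182	2722	541
DM#8	AAATTGACCTGCCCGTGAAGAG	CCTGTTCTTGGGTGGGTGTG	2676	3225	550
DM#9	GGAGTAATCCAGGTCGGTT	TAGATGTGGCGGGTTTTAGG	3079	3505	427
DM#10	GCTACTACAACCCTTCGCTGAC	GTTCGGTTGGTCTCTGCTAGTG	3438	3893	456
DM#11	CTGCGAGCAGTAGCCCAAAC	TGCTAGGGTGAGTGGTAGGAAG	3703	4203	501
DM#12	TTCCTACCACTCACCCTAGCA	AAAAATCAGTGCGAGCTTAGC	4183	4552	370
DM#13	CATCTTTGCAGGCACACTCATC	GATTTTGCGTAGCTGGGTTTGG	4505	5003	499
DM#14	CATAGCAGGCAGTTGAGGTGG	AGGTAGGAGTAGCGTGGTAAGG	4955	5483	529
DM#15	CAAAACCCACCCCATTCCTCC	AATAGTCAACGGTCGGCGAAC	5428	5926	499
DM#16	ACAGTCCAATGCTTCACTCAGC	AGATGGTTAGGTCTACGGAGGC	5861	6345	485
DM#17	AGCAGGAACAGGTTGAACAGTC	GGGAGATTATTCCGAAGCCTGG	6266	6669	404
DM#18	CGGAGGAGGAGACCCCATTC	TGGTAGCGGAGGTGAAATATGC	6572	6831	260
DM#19	TTCCTAGGGTTTATCGTGTGAGC	GTGAATGAAGCCTCCTATGATGG	6747	7088	342
DM#20	GGTGGCCTGACTGGCATTG	GTTGGCTTGAAACCAGCTTTGG	6954	7491	538
DM#21	ACCCTACCACACATTCG	GGAAAATGATTATGAGGGCG	7403	7682	280
DM#22	ACAAGACGCTACTTCCCCTATC	CCTAATGTGGGGACAGCTCATG	7612	8091	480
DM#23	AGTACTCCCGATTGAAGCCCC	GGGCAATGAATGAAGCGAACAG	8011	8560	550
DM#24	ACCTACCTCCCTCACCAAAGC	TGTGCCTTGTGGTAAGAAGTGG	8466	8925	460
DM#25	GCGGGCACAGTGATTATAGG	TGGTTGATATTGCTAGGGTGGC	8854	9076	223
DM#26	CGCCTAACCGCTAACATTACTG	GAGGAGCGTTATGGAGTGGAAG	9001	9335	335
DM#27	TCTCAGCCCTCCTAATGACCTC	GTTGAGCCGTAGATGCCGTC	9271	9793	523
DM#28	CAGAGTACTTCGAGTCTCCCTTC	GACCCTCATCAATAGATGGAGAC	9742	9988	247
DM#29	ATCAACACCCTCCTAGCCTTAC	CCAATTCGGCTCAGTCTAATCC	10083	10407	325
DM#30	CCCTACCATGAGCCCTACAAAC	TAAGAGGGAGTGGGTGTTGAGG	10279	10634	356
DM#31	TCGCTCACACCTCATATCCTCC	AGTCTAGGCCATATGTGTTGGAG	10535	10734	200
DM#32	GCCTAGCCCTACTAGTCTCAATC	AGGTTGGGGAACAGCTAAATAGG	10690	10925	236
DM#33	ATCAACACAACCACCCACAGC	GTTCTTGGGCAGTGAGAGTGAG	10832	11315	484
DM#34	TGAACGCAGGCACATACTTCC	GCCGTGGGCGATTATGAGAATG	11187	11719	533
DM#35	ACAGCCATTCTCATCCAAACCC	GGTCGTAAGCCTCTGTTGTCAG	11654	12195	542
DM#36	GCTCACTCACCCACCACAT	GGATGCGACAATGGATTTTA	12009	12462	454
DM#37	ACCACCCTAACCCTGACTTCC	GCTTGAATGGCTGCTGTGTTG	12358	12848	491
DM#38	GATGATACGCCCGAGCAGATG	TGCTAGGTGTGGTTGGTTGATG	12806	13311	506
DM#39	TCCACTTCAAGTCAACTAGGAC	GGGGATTGTTGTTTGGAAGGG	13249	13785	537
DM#40	GCAGCCGGAAGCCTATTCG	TGAGGTGATGATGGAGGTGGAG	13708	14070	363
DM#41	ATCACACACCGCACAATCCC	ATTGGTGCTGTGGGTGAAAGAG	13930	14371	442
DM#42	TCCTCCCGAATCAACCCTGAC	TCATTGGTCGTGGTTGTAGTCC	14261	14706	446
DM#43	AATAACACACCCGACCACAC	AAGGTAGCGGATGATTCAGC	14548	14992	445
DM#44	TCATCAATCGCCCACATCACTC	ATAGGAGGTGGAGTGCTGCTAG	14936	15341	406
DM#45	AGACAGTCCCACCCTCACAC	GGAGGTCTGCGGCTAGGAG	15256	15743	488
DM#46	CTCCGATCCGTCCCTAACAAAC	GGTTTTGATGTGGATTGGGT	15587	16185	599
DM#47	ACATTACTGCCAGCCACCATG	CCGGAGCGAGGAGAGTAGC	16098	16456	359
DM#48	CAGTCAAATCCCTTCTCGTCCC	TCTGTGTGGAAAGTGGCTGTG	16344	276	502
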