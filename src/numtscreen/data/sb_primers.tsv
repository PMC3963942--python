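id	forward_seq	reverse_seq	target_start	target_end	printed_size_bp
SB#1	GATCACAGGTCTATCACCCTA	TTGGACAACCAGCTATCACCA	1	2027	2027
SB#2	GCACACCCGTCTATGTAGCA	TTCGATGTTGAAGCCTGAGAC	1941	3948	2008
SB#3	CCACACTAGCAGAGACCAAC	GGCTGAGTGAAGCATTGGACT	3869	5883	2015
SB#4	GAAGCTGCTTCTTCGAATTTGC	GGGCGTGATCATGAAAGGTG	5777	7667	1891
SB#5	CAAGTAGGTCTACAAGACGCT	CTGATGCGAGTAATACGGATG	7601	9627	2027
SB#6	TACCACTCCAGCCTAGCCC	TCGTAGGCAGATGGAGCTTG	9510	11593	2084
SB#7	CGGCTATGGTATAATACGCCT	AGCGATGAGAGTAATAGATAGG	11476	13581	2106
SB#8	CCTCACAGGTTTCTACTCCAA	GAGGTCTGGTGAGAATAGTGT	13491	15493	2003
SB#9	GCAGCCCTAGCAACACTCC	CAATGCTATCGCGTGCATACC	15314	90	1346
SB#10	GAACACACAATAGCTAAGACCC	CGGTCTGAACTCAGATCACGTA	1045	3079	2035
SB#11	CGATGTTGGATCAGGACATCC	GGTTGTACGGTAGAACTGCTA	2988	5061	2073
SB#12	CATAGCAGGCAGTTGAGGTG	GATAGGACATAGTGGAAGTGG	4955	7048	2094
SB#13	CTCATCACTAGACATCGTACTA	GCCTGCAGTAATGTTAGCGG	6983	9027	2045
SB#14	CATCAGCCTACTCATTCAACC	GTACGTAGTCTAGGCCATATG	8964	10740	1777
SB#15	GCCTAGCCCTACTAGTCTCAA	CTCAGCCGATGAACAGTTGG	10690	12769	2080
SB#16	CGTTACATGGTCCATCATAGAA	GTCGTGGTTGTAGTCCGTGC	12621	14700	2080
SB#17	CTCCTCAATAGCCATCGCTG	GGGTCTTAGCTATTGTGTGTTC	14462	1045	3193
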