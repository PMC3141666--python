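group	acronym	pattern	n_isos	chromosome	start	end
5	gma-MIR156g	+2/ACAGAAGATAGAGAGCAC/+2	2	Gm19	8895390	8895493
5	gma-MIR159a-3p	+2/TGGATTGAAGGGAGCTCT/+1	4	Gm09	37672410	37672586
4	gma-MIR159a-5p	GAGCTCCTTGAAGTCCAATT/+1	2	Gm09	37672410	37672586
3	gma-MIR159e-3p	+2/TGGATTGAAGGGAGCTC/+2	5	Gm07	9524917	9525127
3	gma-MIR166f	TCTCGGACCAGGCTTCATTC/+1	2	Gm20	43105394	43105500
5	gma-MIR167g	TGAAGCTGCCAGCATGATCTG/+1	2	Gm10	39044877	39044954
3	gma-MIR169g	+1/AGCCAAGAATGACTTGCCGG	2	Gm09	5263992	5264096
3	gma-MIR169h	+1/AGCCAAGAATGACTTGCCGG	2	Gm14	5324798	5324911
5	gma-MIR172c	+1/GAATCTTGATGATGCTGCAG	2	Gm18	2968986	2969138
5	gma-MIR172d	+1/GAATCTTGATGATGCTGCAG/+3	3	Gm14	5548752	5548901
5	gma-MIR172e	+1/GAATCTTGATGATGCTGCAG/+3	3	Gm11	35957808	35957960
3	gma-MIR172h-5p	GCAGCAGCATCAAGATTCAC/+1	2	Gm10	43474725	43474831
3	gma-MIR172i	GCAGCAGCATCAAGATTCAC/+1	2	Gm15	2892962	2893122
3	gma-MIR172j	GCAGCAGCATCAAGATTCAC/+1	2	Gm20	40895747	40895836
5	gma-MIR319a	TTGGACTGAAGGGAGCTCCC/+1	2	Gm05	40832097	40832279
5	gma-MIR319b	TTGGACTGAAGGGAGCTCCC/+1	2	Gm08	1647815	1647987
3	gma-MIR319d	+2/GGACTGAAGGGAGCTCCTTC	2	Gm02	43885398	43885595
3	gma-MIR319f	+1/TGGACTGAAGGGGAGCTCCTTC	2	Gm04	46348798	46348991
3	gma-MIR319j	+2/GGACTGAAGGGAGCTCCTTC	2	Gm14	45953433	45953649
3	gma-miR319k	+2/GGACTGAAGGGAGCTCCTTC	2	Gm17	9436178	9436279
4	gma-MIR396a-3p	+1/TTCAATAAAGCTGTGGGA/+2	3	Gm13	26338134	26338273
5	gma-MIR396a-5p	+1/TCCACAGCTTTCTTGAACTG	2	Gm13	26338134	26338273
4	gma-MIR396b-3p	+1/CTCAAGAAAGCTGTGGGAGA	2	Gm13	26329931	26330056
5	gma-MIR396d-3p	+4/AAGAAAGCTGTGGGAGA/+7	3	Gm17	9053051	9053155
4	gma-MIR396d-5p	TTCCACAGCTTTCTTGAACT/+1	2	Gm17	9053051	9053155
5	gma-MIR396e	+1/TCCACAGCTTTCTTGAACT/+2	4	Gm17	35366535	35366668
3	gma-MIR396g	TTCCACAGCTTTCTTGAACT/+1	2	Gm15	556707	556796
3	gma-MIR396h-3p	+1/TTCAATAAAGCTGTGGGA/+2	3	Gm17	9044861	9044973
3	gma-MIR396h-5p	+1/TCCACAGCTTTCTTGAACT/+1	3	Gm17	9044850	9044984
5	gma-MIR482a-5p	+12/AATGGGCTGATTGG/+5	5	Gm01	7783819	7783913
5	gma-MIR482b-5p	+1/ATGGGGGGATTGGGAAGGA/+2	4	Gm20	35360312	35360406
3	gma-MIR482d-5p	TATGGGGGGATTGGGAAGGA/+2	3	Gm10	48569629	48569723
5	gma-MIR1507a	+3/CATTCCATACATCGTC/+6	8	Gm13	25849777	25849883
5	gma-MIR1507b	+3/CATTCCATACATCGTC/+5	8	Gm17	6190604	6190701
5	gma-MIR1508a	+4/GAAAGGGAAATAGCAGT/+2	6	Gm16	32903737	32903831
5	gma-MIR1508b	+2/GAAAGGGAAATAGCAGTTG	3	Gm09	28530168	28530271
5	gma-MIR1509b	TTAATCAAGGAAATCACGGTT/+1	2	Gm05	7774098	7774206
5	gma-MIR1510a	+3/TTGTTTTACCTATTCCA/+6	7	Gm16	31518908	31519000
5	gma-MIR1510b-3p	TGTTGTTTTACCTATTCCA/+3	4	Gm02	6599299	6599392
4	gma-MIR1510b-5p	+3/GATAGGTAAAACAACTA/+2	5	Gm02	6599299	6599392
5	gma-MIR1511	AACCAGGCTCTGATACCATG/+1	2	Gm18	21161236	21161334
5	gma-MIR1514a	TTCATTTTTAAAATAGGCATT/+1	2	Gm07	43175810	43175908
5	gma-MIR1523	+1/ATGGGATAAATGTGAGCTC/+1	2	Gm02	12253303	12253397
5	gma-MIR2109a-5p	TGCGAGTGTCTTCGCCTCTG/+1	2	Gm04	28532441	28532537
4	gma-MIR2109a-3p	+2/AGGCGTAGATACTCACAC/+2	4	Gm04	28532441	28532537
5	gma-MIR4345	+9/ACTTACAAAGAT/+12	3	Gm14	49069099	49069193
5	gma-MIR4413a	+1/AAGAGAATTGTAAGTCACT/+1	3	Gm19	1788518	1788617
3	gma-MIRSeq07	+14/GACTTG/+14	14	Gm01	44787899	44787988
3	gma-MIRSeq14b	+2/AGAATTTGGCCTCTGTCCA	2	Gm09	28272488	28272562
3	gma-MIRSeq10-3p	+20/G/+20	4	Gm15	31542836	31543058
3	gma-MIRSeq20	CATCGTTGACGCTGACTGT/+3	2	Gm04	35428794	35428950
2	gma-MIR408a	+1/TGCACTGCCTCTTCCCTGGC	2	Gm02	837416	837548
2	gma-MIR408c	+1/TGCACTGCCTCTTCCCTGGC	2	Gm10	36557005	36557130
2	gma-MIR2218a-5p	GGAGATGGGAGGGTCGGTAA/+2	2	Gm10	48574017	48574137
2	gma-MIR3522a	+8/AGACCAAATGAGC/+6	4	Gm15	4318787	4318873
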