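id	mature_sequence	size	chromosome	start	end	length	sense	arm	region
gma-MIR-Seq01	GGACAGUCUCAGGUAGACA	19	Gm04	30764003	30764171	169	-	3p	intergenic
gma-MIR-Seq03	UGAGAAAAGGAGGAUGUCA	19	Gm11	29821812	29821926	115	+	3p	intergenic
gma-MIR-Seq04a	GCUGGAUGUCUUUGAAGGA	19	Gm08	46853906	46853991	86	+	3p	intergenic
gma-MIR-Seq04b	GCUGGAUGUCUUUGAAGGA	19	Gm18	61624611	61624690	80	-	3p	intergenic
gma-MIR-Seq05	AACCCUCAAAGGCUUCCUAG	20	Gm18	61626669	61626771	103	+	5p	intergenic
gma-MIR-Seq06	AGUGGAACUUUGAGGCCUGC	20	Gm08	46848259	46848354	96	+	3p	intergenic
gma-MIR-Seq07	AAAUGACUUGAGAGGUGUAG	20	Gm01	44787899	44787988	90	+	5p	intergenic
gma-MIR-Seq08	CUAAAGAUUGUCCAAAAGGAA	21	Gm14	6763304	6763456	153	+	5p	intergenic
gma-MIR-Seq09	GUAGUGGAUGCCUAGAGGUCC	21	Gm18	61655979	61656075	97	-	3p	intergenic
gma-MIR-Seq10-5p	UAGGAAUUAGUCACUCAGAUC	21	Gm15	31542836	31543058	223	+	5p	intergenic
gma-MIR-Seq10-3p	AUCUCAGUGACUAAUUUCUAG	21	Gm15	31542836	31543058	223	+	3p	intergenic
gma-MIR-Seq11	UUGUUCGAUAAAACUGUUGUG	21	Gm16	5744795	5744863	69	-	5p	intergenic
gma-MIR-Seq12	UCUCUUGAUUCUAGAUGAUGU	21	Gm16	27653048	27653102	55	+	3p	CDS
gma-MIR-Seq13	UGUUGCGGGUAUCUUUGCCUC	21	Gm04	28578972	28579075	104	-	5p	intergenic
gma-MIR-Seq14a	UGAGAAUUUGGCCUCUGUCCA	21	Gm09	28264427	28264515	89	+	5p	intergenic
gma-MIR-Seq14b	UGAGAAUUUGGCCUCUGUCCA	21	Gm09	28272488	28272562	75	+	5p	intergenic
gma-MIR-Seq15a	UUAGAUUCACGCACAAACUUG	21	Gm02	1041996	1042084	89	+	3p	intergenic
gma-MIR-Seq15b	UUAGAUUCACGCACAAACUUG	21	Gm10	1085223	1085322	100	+	3p	intergenic
gma-MIR-Seq16	UUAUAGUCUGACAUCUGGAAU	21	Gm05	9279518	9279737	220	+	5p	intergenic
gma-MIR-Seq17	ACUAUAGAAGUACUUGUGGAGC	22	Gm16	2916844	2917034	191	+	5p	CDS/intronic
gma-MIR-Seq18	CCUCAUUCCAAACAUCAUCUAA	22	Gm09	16565935	16566025	91	-	3p	intergenic
gma-MIR-Seq19	UGAAGAUUUGAAGAAUUUGGGA	22	Gm15	16900161	16900327	167	+	5p	intronic
gma-MIR-Seq20	CAUCGUUGACGCUGACUGUACG	22	Gm04	35428794	35428950	157	-	5p	5'UTR/intronic
gma-MIR-Seq21	CUGAAGGAUCGAUGUAGAAUGCU	23	Gm02	39825520	39825641	122	+	3p	intergenic
gma-MIR-Seq22	CAUCUGAAGGAUAGAACACAUA	22	Gm09	29816467	29816705	239	+	3p	intergenic
gma-MIR-Seq23	AGUUUCGUGACUACAACUUCUGAA	24	Gm15	16900193	16900294	102	-	3p	intergenic
gma-MIR-Seq24	AUGAAAAUCAUUCAUUAUGAUAUC	24	Gm16	28536014	28536181	168	-	3p	intergenic
gma-MIR-Seq25a	GAAAAUGAAUGAUGAGGAUGGGGA	24	Gm11	7787358	7787494	137	-	3p	intergenic
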