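family	acronym	sequence	size	species
MIR170	gma-MIR170	UAUUGGCCUGGUUCACUCAGA	21	ath, aly
MIR395	gma-MIR395a	CUGAAGUGUUUGGGGGAACUC	21	ath, ptc, vvi, sly, rco, aly, csi, osa, sbi, mtr, zma, tae, pab
MIR395	gma-MIR395b	CUGAAGUGUUUGGGGGAACUC	21	ath, ptc, vvi, sly, rco, aly, csi, osa, sbi, mtr, zma, tae, pab
MIR395	gma-MIR395c	CUGAAGUGUUUGGGGGAACUC	21	ath, ptc, vvi, sly, rco, aly, csi, osa, sbi, mtr, zma, tae, pab
MIR397	gma-MIR397a	UCAUUGAGUGCAGCGUUGAUG	21	ath, osa, ptc, bna, vvi, sbi, bdi, rco, aly, csi, zma, pab, sly, hvu
MIR397	gma-MIR397b	UCAUUGAGUGCAGCGUUGAUG	21	ath, osa, ptc, bna, vvi, sbi, bdi, rco, aly, csi, zma, pab, sly, hvu
MIR408	gma-MIR408a	AUGCACUGCCUCUUCCCUGGC	21	ath, ptc, pta, vvi, ahy, aly, csi, osa, sof, zma, ppt, smo, tae, sbi, bdi, rco, aqc
MIR408	gma-MIR408b-5p	CUGGGAACAGGCAGGGCACG	20	ath, ptc, pta, vvi, ahy, aly, csi, osa, sof, zma, ppt, smo, tae, sbi, bdi, rco, aqc
MIR408	gma-MIR408b-3p	AUGCACUGCCUCUUCCCUGGC	21	ath, ptc, pta, vvi, ahy, aly, csi, osa, sof, zma, ppt, smo, tae, sbi, bdi, rco, aqc
MIR408	gma-MIR408c	AUGCACUGCCUCUUCCCUGGC	21	ath, ptc, pta, vvi, ahy, aly, csi, osa, sof, zma, ppt, smo, tae, sbi, bdi, rco, aqc
MIR2118	gma-MIR2118a-5p	GGAGAUGGGAGGGUCGGUAAAG	22	pvc, gso, mtr, osa, zma
MIR2118	gma-MIR2118a-3p	UUGCCGAUUCCACCCAUUCCUA	22	pvc, gso, mtr, osa, zma
MIR2118	gma-MIR2118b-5p	GGAGAUGGGAGGGUCGGUAA	20	pvc, gso, mtr, osa, zma
MIR2118	gma-MIR2118b-3p	UUGCCGAUUCCACCCAUUCCUA	22	pvc, gso, mtr, osa, zma
MIR3522	gma-MIR3522a	UGAGACCAAAUGAGCAGCUGA	21	gso
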