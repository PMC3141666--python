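mirna_id	locus_target	description	pairing
gma-MIR-Seq01	Glyma13g01690	glucuronosyl/glucosyl transferase	-|||||||||||||||-:|
gma-MIR-Seq01	Glyma14g35220	glucuronosyl/glucosyl transferase	-|||||||||||||||-:|
gma-MIR-Seq01	Glyma15g00330	GTPase-activating protein	|||-||:||||||||||-|
gma-MIR-Seq03	Glyma08g22900	LRR-containing proteins	-|||||||||:||||||:|
gma-MIR-Seq03	Glyma07g03200	LRR-containing proteins	-|||||||||:||||||:|
gma-MIR-Seq03	Glyma05g33790	methyltransferase	|-|:|||||||||||:|:|
gma-MIR-Seq03	Glyma04g00810	EF-hand-containing proteins	||:|||||-::||||||||
gma-MIR-Seq03	Glyma11g34320	EF-hand-containing proteins	||:|||:|||:-|||||||
gma-MIR-Seq03	Glyma10g06740	triosephosphate isomerase	--||||:||||||||||||
gma-MIR-Seq05	Glyma07g18570	pyruvate decarboxylase	|-||-:||||||||||||||
gma-MIR-Seq05	Glyma01g29190	pyruvate decarboxylase	|-||-:||||||||||||||
gma-MIR-Seq05	Glyma18g43460	pyruvate decarboxylase	|-||-:||||||||||||||
gma-MIR-Seq06	Glyma08g37480	mt transcription factor	|::-|||||||:||||||:|
gma-MIR-Seq06	Glyma16g26070	serine carboxypeptidase	|||||-|-|:|:||||||||
gma-MIR-Seq07	Glyma04g01020	fructose-bisphosphate aldolase	||||-|:|||||||||||-|
gma-MIR-Seq07	Glyma16g05500	LRR-containing proteins	||:||::|:|:|:|||||||
gma-MIR-Seq07	Glyma19g27280	LRR-containing proteins	||:||::|:|:|:|||||||
gma-MIR-Seq07	Glyma19g07240	translation elongation factor	||-|||-||||||||||||-
gma-MIR-Seq08	Glyma14g23860	oxidoreductase activity	||-||||||||||||||||-|
gma-MIR-Seq08	Glyma13g03430	oxidoreductase activity	||-||||||||||||||||-|
gma-MIR-Seq08	Glyma01g20670	nucleotide excision repair factor	|||||||||-|||:|||||:-
gma-MIR-Seq10	Glyma04g09770	mt oxoglutarate/malate carrier	|:|||::||||||:|:||||:
gma-MIR-Seq11	Glyma15g13500	peroxidase activity	::||-|||||||:|:||||||
gma-MIR-Seq11	Glyma09g02600	peroxidase activity	|:||-|||||||:|:||||||
gma-MIR-Seq12	Glyma08g20670	ATP-dependent RNA helicase	:||||||||||:||:|||||-
gma-MIR-Seq12	Glyma07g01260	ATP-dependent RNA helicase	:||||||||||:||:|||||-
gma-MIR-Seq12	Glyma20g16950	predicted alpha/beta hydrolase	||-||||||||:||||||:|:
gma-MIR-Seq12	Glyma10g23470	predicted alpha/beta hydrolase	||-||||||||:||||||:|:
gma-MIR-Seq12	Glyma19g35390	serine/threonine protein kinase	|||||||||--||-|||||||
gma-MIR-Seq12	Glyma03g32640	serine/threonine protein kinase	|||||||||--||-|||||||
gma-MIR-Seq13	Glyma02g26160	oxidoreductase activity	|-||-||||||||:|||||:|
gma-MIR-Seq13	Glyma10g31690	transcription regulator activity	||||||||-|-|||||::|||
gma-MIR-Seq15	Glyma20g02820	translation initiation factor	--|||||||||||||||||||
gma-MIR-Seq16	Glyma17g20860	LRR-containing proteins	||||||||||||-||:|||||
gma-MIR-Seq16	Glyma05g09440	LRR-containing proteins	||||||||||||-||:|||||
gma-MIR-Seq18	Glyma11g21200	LRR-containing proteins	||:|||||||||||||||||--
gma-MIR-Seq19	Glyma15g37290	LRR-containing proteins	-|||||-||||||||||||||-
gma-MIR-Seq19	Glyma09g34200	LRR-containing proteins	|:|||:|||:|-|||||:||||
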