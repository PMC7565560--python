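ko_id	symbol	product
K00001	adhE	alcohol dehydrogenase
K00016	ldh	L-lactate dehydrogenase
K00123	fdoG	formate dehydrogenase-O major subunit
K00124	fdoH	formate dehydrogenase-O iron-sulfur subunit
K00127	fdoI	formate dehydrogenase-O cytochrome b556 subunit
K00128	aldH	aldehyde dehydrogenase (NAD+)
K00138	aldB	aldehyde dehydrogenase
K00156	poxB	pyruvate dehydrogenase (quinone)
K00192	cdhA	acetyl-CoA decarbonylase/synthase complex subunit alpha
K00195	cdhB	acetyl-CoA decarbonylase/synthase complex subunit epsilon
K00198	cooS	anaerobic carbon-monoxide dehydrogenase
K00362	nirB	nitrite reductase (NADH) large subunit
K00363	nirD	nitrite reductase (NADH) small subunit
K00368	nirK	nitrite reductase (NO-forming), copper type
K00370	narG	nitrate reductase / nitrite oxidoreductase alpha subunit
K00371	narH	nitrate reductase / nitrite oxidoreductase beta subunit
K00374	narI	nitrate reductase gamma subunit
K00376	nosZ	nitrous-oxide reductase
K00380	cysJ	sulfite reductase (NADPH) flavoprotein
K00381	cysI	sulfite reductase (NADPH) hemoprotein
K00390	cysH	phosphoadenosine phosphosulfate reductase
K00392	sir	sulfite reductase (ferredoxin)
K00394	aprA	adenylylsulfate reductase subunit A
K00395	aprB	adenylylsulfate reductase subunit B
K00404	ccoN	cbb3-type cytochrome c oxidase subunit I
K00405	ccoO	cbb3-type cytochrome c oxidase subunit II
K00406	ccoP	cbb3-type cytochrome c oxidase subunit III
K00425	cydA	cytochrome bd ubiquinol oxidase subunit I
K00426	cydB	cytochrome bd ubiquinol oxidase subunit II
K00496	alkB	alkane 1-monooxygenase
K00625	pta	phosphate acetyltransferase
K00656	pflD	formate C-acetyltransferase
K00845	glk	glucokinase
K00850	pfkA	6-phosphofructokinase
K00855	prk	phosphoribulokinase
K00860	cysC	adenylylsulfate kinase
K00873	pyk	pyruvate kinase
K00925	ackA	acetate kinase
K00956	cysN	sulfate adenylyltransferase subunit 1
K00957	cysD	sulfate adenylyltransferase subunit 2
K00958	sat	sulfate adenylyltransferase
K01601	rbcL	ribulose-bisphosphate carboxylase large chain
K01602	rbcS	ribulose-bisphosphate carboxylase small chain
K01610	pckA	phosphoenolpyruvate carboxykinase (ATP)
K01637	aceA	isocitrate lyase
K01638	aceB	malate synthase
K02274	coxA	aa3-type cytochrome c oxidase subunit I
K02275	coxB	aa3-type cytochrome c oxidase subunit II
K02276	coxC	aa3-type cytochrome c oxidase subunit III
K02297	cyoA	cytochrome o ubiquinol oxidase subunit II
K02298	cyoB	cytochrome o ubiquinol oxidase subunit I
K02299	cyoC	cytochrome o ubiquinol oxidase subunit III
K02305	norC	nitric oxide reductase subunit C
K02567	napA	periplasmic nitrate reductase NapA
K02568	napB	cytochrome c-type protein NapB
K02586	nifD	nitrogenase molybdenum-iron protein alpha chain
K02588	nifH	nitrogenase iron protein
K02591	nifK	nitrogenase molybdenum-iron protein beta chain
K02829	qoxA	cytochrome aa3-600 menaquinol oxidase subunit II
K02830	qoxB	cytochrome aa3-600 menaquinol oxidase subunit I
K03385	nrfA	ammonia-forming cytochrome c nitrite reductase
K03841	fbp	fructose-1,6-bisphosphatase I
K04561	norB	nitric oxide reductase subunit B
K06281	hyaB	hydrogenase large subunit
K06282	hyaA	hydrogenase small subunit
K08352	phsA	thiosulfate reductase / polysulfide reductase chain A
K08353	phsB	thiosulfate reductase electron transport protein
K08354	phsC	thiosulfate reductase cytochrome b subunit
K09709	meh	3-methylfumaryl-CoA hydratase
K10535	hao	hydroxylamine dehydrogenase
K10944	amoA	methane/ammonia monooxygenase subunit A
K10945	amoB	methane/ammonia monooxygenase subunit B
K10946	amoC	methane/ammonia monooxygenase subunit C
K11180	dsrA	dissimilatory sulfite reductase alpha subunit
K11181	dsrB	dissimilatory sulfite reductase beta subunit
K11959	urtA	urea transport system substrate-binding protein
K11960	urtB	urea transport system permease protein
K11961	urtC	urea transport system permease protein
K11962	urtD	urea transport system ATP-binding protein
K11963	urtE	urea transport system ATP-binding protein
K13953	adhP	alcohol dehydrogenase, propanol-preferring
K14085	frmA	aldehyde dehydrogenase family 7 member A1
K14138	acsB	acetyl-CoA synthase
K14470	mct	2-methylfumaryl-CoA isomerase
K15023	acsE	5-methyltetrahydrofolate corrinoid/iron sulfur protein methyltransferase
K15230	aclA	ATP-citrate lyase alpha subunit
K15231	aclB	ATP-citrate lyase beta subunit
K15232	ccsA	citryl-CoA synthetase large subunit
K15233	ccsB	citryl-CoA synthetase small subunit
K15864	nirS	nitrite reductase (NO-forming), cytochrome cd1 type
K15876	nrfH	cytochrome c nitrite reductase small subunit
K16936	doxA	thiosulfate dehydrogenase [quinone] small subunit
K16937	doxD	thiosulfate dehydrogenase [quinone] large subunit
K16952	sor	sulfur oxygenase/reductase
K17222	soxA	sulfur-oxidizing protein SoxA
K17223	soxX	sulfur-oxidizing protein SoxX
K17224	soxB	sulfur-oxidizing protein SoxB
K17225	soxC	sulfane dehydrogenase subunit SoxC
K17226	soxY	sulfur-oxidizing protein SoxY
K17227	soxZ	sulfur-oxidizing protein SoxZ
K17229	fccA	sulfide dehydrogenase [flavocytochrome c] cytochrome subunit
K17230	fccB	sulfide dehydrogenase [flavocytochrome c] flavoprotein chain
K19713	tsdA	thiosulfate dehydrogenase
K20938	almA	flavin-binding monooxygenase AlmA
K21307	soeA	sulfite dehydrogenase (quinone) subunit A
K21308	soeB	sulfite dehydrogenase (quinone) subunit B
K21309	soeC	sulfite dehydrogenase (quinone) subunit C
K22622	soxD	sulfane dehydrogenase subunit SoxD
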