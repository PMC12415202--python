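lbd_id	organism	receptor_class	domain_family	ligand	ligand_class	evidence	source
K1		MCP	sCache_2	L-lactate	carboxylic acid	experimental	itc
C1		MCP	sCache_2	L-lactate	carboxylic acid	experimental	itc
sc2-a		MCP	sCache_2	L-lactate	carboxylic acid	experimental	tsa
sc2-b		MCP	sCache_2	L-lactate	carboxylic acid	experimental	tsa
sc2-c		MCP	sCache_2	pyruvate	carboxylic acid	experimental	tsa
sc33-a		MCP	sCache_3_3	formate	carboxylic acid	experimental	tsa
B6	Catenibacterium mitsuokai	HK	SMP_2	indole	indole	experimental	itc
A5		MCP	dCache_1	amino acids	amino acid	experimental	tsa
B9		MCP	dCache_1	L-threonine	amino acid	experimental	itc
J6		MCP	dCache_1	ethylamine	amine	experimental	itc
J6		MCP	dCache_1	methylamine	amine	experimental	itc
M3		DGC	dCache_1	purines	purine	experimental	tsa
D8		MCP	dCache_1	succinate	carboxylic acid	experimental	itc
D8		MCP	dCache_1	methylmalonate	carboxylic acid	experimental	tsa
D8		MCP	dCache_1	maleate	carboxylic acid	experimental	tsa
D8		MCP	dCache_1	itaconate	carboxylic acid	experimental	tsa
H8		MCP	dCache_1	uracil	pyrimidine	experimental	tsa
H8		MCP	dCache_1	acetate	carboxylic acid	experimental	tsa
A4		MCP	dCache_1	uracil	pyrimidine	experimental	itc
A4		MCP	dCache_1	acetate	carboxylic acid	experimental	itc
M8		DGC	dCache_1	uracil	pyrimidine	experimental	tsa
M8		DGC	dCache_1	acetate	carboxylic acid	experimental	tsa
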