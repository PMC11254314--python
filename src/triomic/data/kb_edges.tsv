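# Directed reaction edges: pathway_id, source, target, catalyst genes.
# Reversible reactions appear as two opposed rows (e.g. uracil/uridine).
purine	gdp	dgdp	Rrm2
purine	dgdp	dgmp
purine	dgmp	deoxyguanosine
purine	deoxyguanosine	guanine
purine	guanine	xanthine
purine	xanthine	uric acid
pyrimidine	udp	dudp	Rrm2
pyrimidine	dudp	dump
pyrimidine	dump	deoxyuridine
pyrimidine	deoxyuridine	uracil
pyrimidine	uracil	uridine
pyrimidine	uridine	uracil
ufa	palmitoyl-coa	palmitic acid	Acot2
ufa	palmitoyl-coa	stearoyl-coa	Elovl6
ufa	stearoyl-coa	stearic acid	Acot2
ufa	stearoyl-coa	oleoyl-coa	Scd1
ufa	oleoyl-coa	oleic acid	Acot2
ufa	linoleoyl-coa	linoleic acid	Acot2
cysmet	l-methionine	s-adenosylmethionine	Mat2a
cysmet	s-adenosylmethionine	s-adenosylhomocysteine
cysmet	s-adenosylmethionine	5'-methylthioadenosine
cysmet	s-adenosylhomocysteine	l-homocysteine
cysmet	l-homocysteine	l-cystathionine	Cbs
cysmet	l-cystathionine	l-cysteine	Cth
cysmet	l-cysteine	3-sulfinoalanine	Cdo1
cysmet	3-sulfinoalanine	3-sulfinylpyruvate
aminosugar	glucosamine 6-phosphate	n-acetylglucosamine 6-phosphate	Gnpnat1
aminosugar	n-acetylglucosamine 6-phosphate	n-acetylglucosamine 1-phosphate
aminosugar	n-acetylglucosamine 1-phosphate	udp-n-acetylglucosamine	Uap1
aminosugar	udp-n-acetylglucosamine	d-glucose 1-phosphate
porphyrin	protoporphyrin ix	heme	Fech
porphyrin	heme	biliverdin	Cp,Hmox1
porphyrin	biliverdin	bilirubin	Blvra
glycerophospholipid	glycerone phosphate	sn-glycerol 3-phosphate	Gpd1
glycerophospholipid	sn-glycerol 3-phosphate	1-acyl-sn-glycerol 3-phosphate	Gpat1
glycerophospholipid	1-acyl-sn-glycerol 3-phosphate	phosphatidate
glycerophospholipid	phosphatidate	phosphatidylcholine
glycerophospholipid	phosphatidylcholine	sn-glycero-3-phosphocholine	Pla2g4a
glycolysis	d-glucose	glucose 6-phosphate	Hk2
glycolysis	glucose 6-phosphate	fructose 6-phosphate	Gpi1
glycolysis	fructose 6-phosphate	pyruvate	Pkm
tca	oxaloacetate	citrate	Cs
tca	citrate	isocitrate	Aco2
tca	isocitrate	2-oxoglutarate	Idh1
arginine	l-citrulline	l-argininosuccinate	Ass1
arginine	l-argininosuccinate	l-arginine	Asl
arginine	l-arginine	l-ornithine	Arg1
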