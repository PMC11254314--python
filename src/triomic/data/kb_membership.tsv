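# Mini pathway knowledge base: hand-curated, coarse-granularity membership.
# Seven signal pathways plus three decoys. Not a KEGG mirror; currency
# metabolites (ATP, H2O, ...) are deliberately excluded.
purine	Purine metabolism	g:Rrm2	m:gdp	m:dgdp	m:dgmp	m:deoxyguanosine	m:guanine	m:xanthine	m:uric acid
pyrimidine	Pyrimidine metabolism	g:Rrm2	m:udp	m:dudp	m:dump	m:deoxyuridine	m:uracil	m:uridine
ufa	Biosynthesis of unsaturated fatty acids	g:Acot2	g:Elovl6	g:Scd1	m:palmitoyl-coa	m:palmitic acid	m:stearoyl-coa	m:stearic acid	m:oleoyl-coa	m:oleic acid	m:linoleoyl-coa	m:linoleic acid
cysmet	Cysteine and methionine metabolism	g:Mat2a	g:Cbs	g:Cth	g:Cdo1	m:l-methionine	m:s-adenosylmethionine	m:s-adenosylhomocysteine	m:l-homocysteine	m:l-cystathionine	m:l-cysteine	m:3-sulfinoalanine	m:3-sulfinylpyruvate	m:5'-methylthioadenosine
aminosugar	Amino sugar and nucleotide sugar metabolism	g:Gnpnat1	g:Uap1	m:glucosamine 6-phosphate	m:n-acetylglucosamine 6-phosphate	m:n-acetylglucosamine 1-phosphate	m:udp-n-acetylglucosamine	m:d-glucose 1-phosphate
porphyrin	Porphyrin metabolism	g:Cp	g:Hmox1	g:Fech	g:Blvra	m:protoporphyrin ix	m:heme	m:biliverdin	m:bilirubin
glycerophospholipid	Glycerophospholipid metabolism	g:Gpd1	g:Gpat1	g:Pla2g4a	m:glycerone phosphate	m:sn-glycerol 3-phosphate	m:1-acyl-sn-glycerol 3-phosphate	m:phosphatidate	m:phosphatidylcholine	m:sn-glycero-3-phosphocholine
glycolysis	Glycolysis / gluconeogenesis (decoy)	g:Hk2	g:Gpi1	g:Pkm	m:d-glucose	m:glucose 6-phosphate	m:fructose 6-phosphate	m:pyruvate
tca	Citrate cycle (decoy)	g:Cs	g:Aco2	g:Idh1	m:oxaloacetate	m:citrate	m:isocitrate	m:2-oxoglutarate
arginine	Arginine biosynthesis (decoy)	g:Ass1	g:Asl	g:Arg1	m:l-citrulline	m:l-argininosuccinate	m:l-arginine	m:l-ornithine
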