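species	COQ2:204	COQ2:243	MEV1:71	TDO2:133	ETFDH:437
Caenorhabditis elegans	L	S	G	P	F
Homo sapiens	F	A	I	A	C
Hydra vulgaris	L	A	G	P	F
Nematostella vectensis	L	S	G	P	F
Exaiptasia pallida	F	A	G	P	F
Actinia tenebrosa	M	A	G	P	F
Diadumene lineata	M	A	-	-	F
Xenia sp. Carnegie-2017	I	A	I	A	F
Dendronephthya gigantea	F	A	G	S	F
Orbicella faveolate	F	A	I	P	F
Stylophora pistillata	F	A	I	P	F
Acropora millepora	F	A	I	P	F
Acropora digitifera	F	A	I	P	F
Pocillopora damicornis	F	A	-	P	F
Blastomussa wellsi	F	A	-	-	F
Montipora capitata	F	A	-	-	F
Galaxea fascicularis	F	A	-	-	F
Haliclystus octoradiatus	M	A	-	-	F
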