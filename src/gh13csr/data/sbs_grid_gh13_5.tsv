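record	2GJP:SBS-I:W439	2GJP:SBS-I:W469	2GJP:SBS-II:W347	2GJP:SBS-III:Y363	6TOZ:SBS-I:F257	6TOZ:SBS-I:Y358	3BC9:SBS-I:Y460	3BC9:SBS-I:W488	3BC9:SBS-II:W260	3BC9:SBS-II:W287	3BC9:SBS-III:W306	3BC9:SBS-III:W310
AWX66236_Alicyclobacillus_sp_18711	T	N	W	Y	F	Y	D	I	W	W	W	G
AAQ01675_Alkalimonas_amylolytica	S	Y	N	V	F	V	I	F	W	-	N	-
CAL14744_Anoxybacillus_flavithermus	W	W	W	Y	F	Y	P	I	W	W	W	G
AEW07376_Bacillus_acidicola	W	W	W	Y	F	Y	P	I	W	W	W	G
AAA22191_Bacillus_amyloliquefaciens	R	W	W	Y	F	Y	T	T	W	W	W	G
ABY86223_Bacillus_cereus	W	W	W	Y	F	Y	P	T	W	W	W	G
CAD26699_Bacillus_halmapalus	W	W	W	Y	F	Y	E	I	W	W	W	G
AAA22226_Bacillus_licheniformis	R	W	W	Y	F	Y	T	T	W	W	W	G
AEM05860_Bacillus_licheniformis	R	W	W	Y	F	Y	T	T	W	W	W	G
AAK00598_Bacillus_megaterium	W	W	W	Y	F	Y	P	T	W	W	W	G
AGN35141_Bacillus_paralicheniformis	R	W	W	Y	F	Y	T	T	W	W	W	G
AAR68734_Bacillus_sp	W	W	W	Y	F	Y	S	I	W	W	W	G
AAA22231_Bacillus_sp_707	W	W	W	Y	F	Y	E	I	W	W	W	G
BAF03567_Bacillus_sp_JAMB_204	R	W	W	Y	F	Y	S	T	Y	Y	W	G
CAC39917_Bacillus_sp_KSM_K38	W	W	W	Y	F	Y	D	I	W	W	W	G
AAB18785_Bacillus_sp_MK_716	W	W	W	Y	F	Y	P	I	W	W	W	G
AAA63900_Bacillus_sp_TS_23	W	W	W	Y	F	Y	P	I	W	W	W	G
ABW87262_Bacillus_sp_YX_YX1	R	W	W	Y	F	Y	T	T	W	W	W	G
AAF00567_Cytophaga_sp	R	Y	W	Y	F	Y	P	T	W	W	W	G
AAC74994_Escherichia_coli	T	E	W	V	F	V	P	A	W	H	W	G
AFZ41193_Exiguobacterium_sp_DAU5	W	W	W	Y	F	Y	N	T	W	W	S	G
AAA22235_Geobacillus_stearothermophilus	W	W	W	Y	F	Y	P	I	W	W	W	G
ABX83871_Geobacillus_thermodenitrificans	W	R	W	R	F	R	P	I	W	W	F	K
AFC87833_Geobacillus_thermoleovorans	W	W	W	Y	F	Y	P	I	W	W	W	G
ACL70573_Halothermothrix_orenii	W	Y	S	V	F	V	Y	W	W	W	W	W
CAQ30277_Nostoc_sp_PCC_7119	W	W	W	Y	F	Y	P	A	Y	Y	D	G
AAA27110_Salmonella_typhimurium	T	E	W	V	F	V	P	A	W	H	W	G
BAA24178_Streptococcus_equinus	R	Y	W	L	Y	L	E	I	W	Y	N	G
AAA97431_Streptococcus_equinus	R	Y	W	L	Y	L	E	I	W	Y	N	G
AAN59233_Streptococcus_mutans	R	W	W	I	Y	I	E	I	W	Y	S	G
CCD30600_uncultured_bacterium	R	Y	K	I	F	I	Y	Y	W	W	Y	R
ALP73597_Vibrio_alginolyticus	W	W	W	Y	F	Y	W	A	W	W	W	G
ABK62854_Histoplasma_capsulatum	R	Y	F	Y	L	Y	D	V	W	F	W	G
ABS11196_Paracoccidioides_brasiliensis	R	Y	F	Y	F	Y	E	L	W	Y	W	G
BAW15172_Pholiota_microspora	R	W	N	Y	F	Y	D	N	W	W	W	G
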