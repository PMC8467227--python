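record	3BLP:SBS-I:Y276	3BLP:SBS-I:W284	3BLP:SBS-II:W316	3BLP:SBS-II:W388	3BLP:SBS-III:W203	3BLP:SBS-IV:W134
ABL09312_Acarus_siro	T	W	F	W	W	N
BAB85635_Anguilla_japonica	Y	W	W	W	W	W
AAL37207_Crassostrea_gigas	W	W	Y	W	W	W
AAL37183_Crassostrea_gigas	W	W	F	W	W	W
AAD38942_Dermatophagoides_pteronyssinus	W	W	F	W	W	N
AAD38943_Euroglyphus_maynei	W	W	F	W	W	N
AAC60246_Gallus_gallus	Y	W	W	W	W	W
ABO26610_Haliotis_discus_discus	Y	W	F	W	W	T
BAM74656_Haliotis_discus_hannai	Y	W	F	W	W	T
AAA51724_Homo_sapiens (pancreas)	Y	W	W	W	W	W
AAH63129_Homo_sapiens (saliva)	Y	W	W	W	W	W
AAA37221_Mus_musculus	Y	W	W	W	W	F
AAA37230_Mus_musculus	Y	W	W	W	W	W
H2N0D4_Oryzias_latipes	Y	W	W	W	W	L
CAA68065_Pecten_maximus	N	W	F	W	W	W
CAA54524_Penaeus_vannamei	Y	W	R	W	W	F
CAB65552_Penaeus_vannamei	Y	W	R	W	W	F
AAF65827_Pseudopleuronectes_americanus	Y	W	W	W	W	C
AAA40725_Rattus_norvegicus	Y	W	W	W	W	W
AAH88228_Rattus_norvegicus	Y	W	W	W	W	F
P83053_Struthio_camelus	Y	W	W	W	W	W
AAF02828_Sus_scrofa	Y	W	W	W	W	W
CAC87125_Tetraodon_nigroviridis	Y	W	W	W	W	L
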