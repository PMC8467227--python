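record	2GUY:SBS-I:Y382	2GUY:SBS-I:W385
AAA85446_Paenibacillus_polymyxa	G	R
CAA49465_Thermoactinomyces_vulgaris	G	A
BAD06003_Aspergillus_awamori	Y	D
BAD06002_Aspergillus_awamori	Y	W
AAF14264_Aspergillus_flavus	Y	W
BAD01051_Aspergillus_kawachii	Y	W
BAA22993_Aspergillus_kawachii	Y	D
EAA64850_Aspergillus_nidulans	Y	Y
AAF17100_Aspergillus_nidulans	S	T
P56271_Aspergillus_niger	Y	D
CAK44871_Aspergillus_niger	Y	W
CAK40249_Aspergillus_niger	V	Y
CAK41088_Aspergillus_niger	S	Y
CAA31218_Aspergillus_oryzae	Y	W
BAA01255_Aspergillus_shirousami	Y	W
AEB80431_Aspergillus_tubingensis	Y	D
BAA12010_Cryptococcus_sp_S_2	Y	Q
ABG48762_Fusicoccum_sp_BCC4124	Y	W
AAO12212_Lipomyces_kononenkoae	D	V
AAC49622_Lipomyces_spencermartinsiae	Y	W
AAN75021_Lipomyces_starkeyi	Y	W
AFD54462_Malbranchea_cinnamomea	T	D
ABF72529_Ophiostoma_floccosum	S	S
EPS26265_Penicillium_oxalicum	S	N
ABO42285_Phanerochaete_chrysosporium	S	E
BAW15173_Pholiota_microspora	K	Q
BAF98616_Pichia_burtonii	T	S
AGJ52081_Rhizomucor_pusillus	T	M
ADL28123_Rhizopus_oryzae	T	M
ADD80242_Saccharomycopsis_fibuligera	S	S
ABS76467_Saitozyma_flava	Y	Q
CAB11471_Schizosaccharomyces_pombe	S	H
CAB40006_Schizosaccharomyces_pombe	S	Q
CAA34162_Schwanniomyces_occidentalis	Y	S
CAA51912_Schwanniomyces_occidentalis	Y	D
ACN82436_Sclerotinia_sclerotiorum	Y	Y
CAA03110_Thermomyces_lanuginosus	S	K
BAG69580_Trichoderma_viride	N	K
CAJ21046_Valsaria_rubricosa	N	V
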