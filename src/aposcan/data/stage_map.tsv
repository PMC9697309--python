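go_id	stage	name
GO:0009908	flower_ovule_formation	flower development
GO:0048481	flower_ovule_formation	plant ovule development
GO:0007143	meiosis	female meiotic nuclear division
GO:0007140	meiosis	male meiotic nuclear division
GO:0007129	meiosis	homologous chromosome pairing at meiosis
GO:0007091	meiosis	metaphase/anaphase transition of mitotic cell cycle
GO:0009554	meiosis	megasporogenesis
GO:0009553	embryo_sac_gametogenesis	embryo sac development
GO:0048229	embryo_sac_gametogenesis	gametophyte development
GO:0009793	embryo_seed_formation	embryo development ending in seed dormancy
GO:0048316	embryo_seed_formation	seed development
GO:0009556	male_functions	microsporogenesis
GO:0009555	male_functions	pollen development
GO:0048658	male_functions	anther wall tapetum development
GO:0060321	male_functions	acceptance of pollen
GO:0009846	male_functions	pollen germination
GO:0009860	male_functions	pollen tube growth
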