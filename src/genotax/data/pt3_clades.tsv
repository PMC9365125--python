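genome_id	clade
Al_spongicola	Aliamphritea
Al_ceti	Aliamphritea
A_atlantica	Amphritea
A_japonica	Amphritea
A_balenae	Amphritea
A_opalescens	Amphritea
A_pacifica	Amphritea
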