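contig	position	gene_locus
Chr_2	144021434	ARHGAP15
Chr_5	21243489
Chr_6	102952779
Chr_7	7985552	GLCCI1
Chr_14	51737509
Chr_15	31819131	RYR3
Chr_17	62067756	PRKCA
Chr_18	12481262	SPIRE1
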