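label	fwd	rev	reported_product_nt
Chr5:21243489_L1+	ttgcctaagcttcccataca	TGAACCCGGTACCTCAGATG	539
Chr5:21243489_L1-	ttgcctaagcttcccataca	tgatccatgtcaataatgaggtc	677
TRDN_L1+	tttcatgccatctctatattccaa	TGAACCCGGTACCTCAGATG	477
TRDN_L1-	tttcatgccatctctatattccaa	aaaaacaggcctgagattgc	690
GLCCI1_L1+	tcctcatacaaacttgtgaagtgat	TGAACCCGGTACCTCAGATG	666
GLCCI1_L1-	tcctcatacaaacttgtgaagtgat	ttcaagcttcatctaatgaaagaaaa	682
PRKCA_L1+	tgtgcaaatttcaccccata	TGAACCCGGTACCTCAGATG	527
PRKCA_L1-	tgtgcaaatttcaccccata	ccatagagcagtgacccaca	622
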