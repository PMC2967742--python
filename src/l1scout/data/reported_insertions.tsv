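contig	position	child_genotype	father_genotype	mother_genotype	l1_orientation	gene_locus	entrez_id	gene_orientation	pcr_validated
Chr_2	144021434	+/-	+/-	N	-	ARHGAP15	55843	+	0
Chr_3	38601086	+/-	+/-	+/-	+	SCN5A	6331	-	0
Chr_3	82073683	+/-	Y	N	-				0
Chr_3	125073416	Y	+/-	Y	+	MYLK	4638	-	0
Chr_3	187854832	+/-	N	Y	+				0
Chr_4	132401098	+/-	+/-	+/-	-				0
Chr_4	147444745	+/-	N	Y	+	SLC10A7	84068	-	0
Chr_5	21243489	Y	+/-	+/-	+				1
Chr_5	89486537	Y	Y	Y	+				0
Chr_6	102952779	+/-	+/-	N	-				0
Chr_6	123895635	+/-	+/-	N	-	TRDN	10345	-	1
Chr_7	7985552	+/-	N	+/-	+	GLCCI1	113263	+	1
Chr_7	53619996	+/-	Y	?/?	-				0
Chr_10	124445220	Y	+/-	Y	+				0
Chr_11	109883089	Y	N	+/-	-				0
Chr_12	125368882	+/-	N	+/-	-				0
Chr_13	60360333	Y	Y	+/-	-				0
Chr_14	51737509	Y	Y	Y	-				0
Chr_15	31819131	Y	+/-	+/-	-	RYR3	6263	+	0
Chr_15	54038444	+/-	N	+/-	+	NEDD4	4734	-	0
Chr_17	62067756	+/-	+/-	N	+	PRKCA	5578	+	1
Chr_18	12481262	+/-	N	+/-	+	SPIRE1	56907	-	0
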