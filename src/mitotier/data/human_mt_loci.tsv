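# Standard human mitochondrial gene map (1-based inclusive, NC_012920.1 coordinates).
# Columns: name  type  start  end  strand  frame
# The control region spans the circular origin (start > end).
# frame = genomic position of the first base of codon 1 (CDS only).
MT-CR	regulatory	16024	576	+	.
MT-TF	tRNA	577	647	+	.
MT-RNR1	rRNA	648	1601	+	.
MT-TV	tRNA	1602	1670	+	.
MT-RNR2	rRNA	1671	3229	+	.
MT-TL1	tRNA	3230	3304	+	.
MT-ND1	CDS	3307	4262	+	3307
MT-TI	tRNA	4263	4331	+	.
MT-TQ	tRNA	4329	4400	-	.
MT-TM	tRNA	4402	4469	+	.
MT-ND2	CDS	4470	5511	+	4470
MT-TW	tRNA	5512	5579	+	.
MT-TA	tRNA	5587	5655	-	.
MT-TN	tRNA	5657	5729	-	.
MT-TC	tRNA	5761	5826	-	.
MT-TY	tRNA	5826	5891	-	.
MT-CO1	CDS	5904	7445	+	5904
MT-TS1	tRNA	7446	7514	-	.
MT-TD	tRNA	7518	7585	+	.
MT-CO2	CDS	7586	8269	+	7586
MT-TK	tRNA	8295	8364	+	.
MT-ATP8	CDS	8366	8572	+	8366
MT-ATP6	CDS	8527	9207	+	8527
MT-CO3	CDS	9207	9990	+	9207
MT-TG	tRNA	9991	10058	+	.
MT-ND3	CDS	10059	10404	+	10059
MT-TR	tRNA	10405	10469	+	.
MT-ND4L	CDS	10470	10766	+	10470
MT-ND4	CDS	10760	12137	+	10760
MT-TH	tRNA	12138	12206	+	.
MT-TS2	tRNA	12207	12265	+	.
MT-TL2	tRNA	12266	12336	+	.
MT-ND5	CDS	12337	14148	+	12337
MT-ND6	CDS	14149	14673	-	14673
MT-TE	tRNA	14674	14742	-	.
MT-CYB	CDS	14747	15887	+	14747
MT-TT	tRNA	15888	15953	+	.
MT-TP	tRNA	15956	16023	-	.
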