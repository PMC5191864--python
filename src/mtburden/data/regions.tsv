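# Region map of the human mitochondrial reference genome (NC_012920, rCRS).
# Coordinates are 1-based inclusive. The control region wraps the origin and is
# stored as two segments sharing the name D-loop. strand: heavy = sense strand
# equals the reference plus strand; light = gene is read from the reverse
# complement. codon_offset is the reading-frame offset of `start` and is only
# meaningful for protein_coding records ('.' otherwise).
name	region_class	start	end	strand	codon_offset
MT-TF	tRNA	577	647	heavy	.
MT-RNR1	rRNA	648	1601	heavy	.
MT-TV	tRNA	1602	1670	heavy	.
MT-RNR2	rRNA	1671	3229	heavy	.
MT-TL1	tRNA	3230	3304	heavy	.
MT-ND1	protein_coding	3307	4262	heavy	0
MT-TI	tRNA	4263	4331	heavy	.
MT-TQ	tRNA	4329	4400	light	.
MT-TM	tRNA	4402	4469	heavy	.
MT-ND2	protein_coding	4470	5511	heavy	0
MT-TW	tRNA	5512	5579	heavy	.
MT-TA	tRNA	5587	5655	light	.
MT-TN	tRNA	5657	5729	light	.
MT-TC	tRNA	5761	5826	light	.
MT-TY	tRNA	5826	5891	light	.
MT-CO1	protein_coding	5904	7445	heavy	0
MT-TS1	tRNA	7446	7514	light	.
MT-TD	tRNA	7518	7585	heavy	.
MT-CO2	protein_coding	7586	8269	heavy	0
MT-TK	tRNA	8295	8364	heavy	.
MT-ATP8	protein_coding	8366	8572	heavy	0
MT-ATP6	protein_coding	8527	9207	heavy	0
MT-CO3	protein_coding	9207	9990	heavy	0
MT-TG	tRNA	9991	10058	heavy	.
MT-ND3	protein_coding	10059	10404	heavy	0
MT-TR	tRNA	10405	10469	heavy	.
MT-ND4L	protein_coding	10470	10766	heavy	0
MT-ND4	protein_coding	10760	12137	heavy	0
MT-TH	tRNA	12138	12206	heavy	.
MT-TS2	tRNA	12207	12265	heavy	.
MT-TL2	tRNA	12266	12336	heavy	.
MT-ND5	protein_coding	12337	14148	heavy	0
MT-ND6	protein_coding	14149	14673	light	0
MT-TE	tRNA	14674	14742	light	.
MT-CYB	protein_coding	14747	15887	heavy	0
MT-TT	tRNA	15888	15953	heavy	.
MT-TP	tRNA	15956	16023	light	.
D-loop	control_region	16024	16569	heavy	.
D-loop	control_region	1	576	heavy	.
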