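# Human mtDNA feature table in rCRS (NC_012920) coordinates; 1-based closed intervals.
# strand: H = heavy, L = light. Overlapping genes (ATP8/ATP6, ND4L/ND4, ATP6/CO3) are real.
name	start	end	strand	type
CR_5prime	1	576	H	control
TRNF	577	647	H	tRNA
RNR1	648	1601	H	rRNA
TRNV	1602	1670	H	tRNA
RNR2	1671	3229	H	rRNA
TRNL1	3230	3304	H	tRNA
ND1	3307	4262	H	protein
TRNI	4263	4331	H	tRNA
TRNQ	4329	4400	L	tRNA
TRNM	4402	4469	H	tRNA
ND2	4470	5511	H	protein
TRNW	5512	5579	H	tRNA
TRNA	5587	5655	L	tRNA
TRNN	5657	5729	L	tRNA
TRNC	5761	5826	L	tRNA
TRNY	5826	5891	L	tRNA
CO1	5904	7445	H	protein
TRNS1	7446	7514	L	tRNA
TRND	7518	7585	H	tRNA
CO2	7586	8269	H	protein
TRNK	8295	8364	H	tRNA
ATP8	8366	8572	H	protein
ATP6	8527	9207	H	protein
CO3	9207	9990	H	protein
TRNG	9991	10058	H	tRNA
ND3	10059	10404	H	protein
TRNR	10405	10469	H	tRNA
ND4L	10470	10766	H	protein
ND4	10760	12137	H	protein
TRNH	12138	12206	H	tRNA
TRNS2	12207	12265	H	tRNA
TRNL2	12266	12336	H	tRNA
ND5	12337	14148	H	protein
ND6	14149	14673	L	protein
TRNE	14674	14742	L	tRNA
CYB	14747	15887	H	protein
TRNT	15888	15953	H	tRNA
TRNP	15956	16023	L	tRNA
CR_3prime	16024	16569	H	control
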