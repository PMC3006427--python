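# Haplogroup C and D nomenclature fixture (rCRS-relative variant names).
# Columns: label, parent ('-' = root), defining variants, negative markers, status.
# status "paper": motif as stated for the clade in the study this fixture encodes.
# status "backbone": connective node whose full motif is not restated there; such rows
#   carry either an empty defining set ('.') or SYNTHETIC placeholder markers chosen to
#   keep sibling clades distinguishable in tests. Do not interpret backbone markers as
#   real nomenclature. Control-region context markers 16223/16362 are attached at D4 so
#   that stated HVS1 motifs resolve correctly for control-region-only profiles.
label	parent	defining	negative	status
M	-	.	.	backbone
C	M	.	.	backbone
C1	C	.	.	backbone
C1a	C1	.	.	backbone
C4	C	.	.	backbone
C4a'b'c	C4	2232.1A	.	paper
C4e	C4	151,152,7307,15479	2232.1A	paper
C4a	C4a'b'c	6026	.	backbone
C4b	C4a'b'c	11969	.	backbone
C4c	C4a'b'c	5899	.	backbone
C4a1	C4a	9545	.	backbone
C4a1a	C4a1	6234	.	backbone
C4a1a1	C4a1a	12672	.	backbone
C4a1a2	C4a1a	13740	.	backbone
C4a1a2b	C4a1a2	8485	.	backbone
C4b2	C4b	3816	.	backbone
C4b4	C4b	5442	.	backbone
C4b5	C4b	9296	.	backbone
C4b6	C4b	10685	.	backbone
C4b7	C4b	12361	.	backbone
C4b8	C4b	14053	.	backbone
C5	C	.	.	backbone
C5a	C5	8589	.	backbone
C5a2	C5a	11944	.	backbone
C5a2a	C5a2	7867	.	backbone
C5b	C5	5027	.	backbone
C5b1	C5b	6179	.	backbone
C5b1a	C5b1	9962	.	backbone
C5c	C5	10454,16093,16518T,16527	.	paper
C5c1	C5c	16234	.	paper
C5c1a	C5c1	7694	.	paper
C5c2	C5c	16291	.	paper
C7	C	5913	.	backbone
C7a	C7	8473	.	backbone
C7a1	C7a	11151	.	backbone
C7a1a	C7a1	14502	.	backbone
D	M	4883,5178A	.	backbone
D4	D	3010,8414,14668,16223,16362	.	backbone
D2	D4	9181	.	backbone
D4b	D4	8020,16319	.	backbone
D4b1	D4b	15440	.	backbone
D4b1a	D4b1	5147	.	backbone
D4b1a2	D4b1a	6473	.	backbone
D4b1a2a	D4b1a2	9667	.	backbone
D4b1a2a1	D4b1a2a	16173	.	paper
D4b1a2a1a	D4b1a2a1	16093	.	paper
D4b1a2a1b	D4b1a2a1	16129	.	paper
D4b1a2a2	D4b1a2a	12654	.	backbone
D4e	D4	4047	.	backbone
D4e4	D4e	6380	.	backbone
D4e4a	D4e4	7256	.	backbone
D4e4b	D4e4	10181	.	backbone
D4j	D4	4539	.	backbone
D4j4	D4j	5261	.	backbone
D4j5	D4j	6293	.	backbone
D4j7	D4j	7424	.	backbone
D4j8	D4j	8701	.	backbone
D4j9	D4j	9723	.	backbone
D4j10	D4j	10872	.	backbone
D4l	D4	11485	.	backbone
D4l2	D4l	12405	.	backbone
D4m	D4	13542	.	backbone
D4m2	D4m	14279	.	backbone
D4m2a	D4m2	15106	.	backbone
D5	D	5351	.	backbone
D5a	D5	6572	.	backbone
D5a3	D5a	16360	.	paper
D5a3a	D5a3	16126,16136	.	paper
D6	D	7618	.	backbone
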