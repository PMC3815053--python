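# Published per-gene SNP/genotype table (typed verbatim). '?' = genotype
# unassignable (flanking markers disagree); '-' = not applicable; intronic '-'
# rows are single-exon genes.
gene	chromosome	gt_LGXSM-6	gt_LGXSM-35	gt_LGXSM-5	gt_LGXSM-33	total_snps	total_hc	noncoding_total	noncoding_hc	upstream	upstream_hc	utr5	utr5_hc	intronic	intronic_hc	utr3	utr3_hc	downstream	downstream_hc	exonic	exonic_hc	synonymous	nonsynonymous	significance	position	exon	substitution
Axin2	11	SS	SS	LL	SS	37	4	32	1	1	0	0	0	30	1	1	0	0	0	5	3	3	2	Np; PolyPhen-2	108,805,010; 108,803,724	5; 7	Arg:648:Cys; Tyr:474:His
Wnt16	6	LL	LL	?	SS	81	5	79	5	5	0	3	1	47	3	3	0	21	1	2	0	2	0	Np	-	-	-
Pcna	2	LL	SS	?	SS	6	1	5	0	2	0	0	0	1	0	0	0	2	0	1	1	1	0	Np	-	-	-
Xrcc2	5	LL	LL	LL	SS	100	4	98	2	30	0	0	0	59	2	2	0	7	0	2	2	1	1	Np	25,204,113	2	Gly:26:Ala
Il6	5	LL	LL	LL	SS	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	-	-	-	-
Cebpb	2	?	LL	LL	SS	0	0	0	0	0	0	0	0	-	-	0	0	0	0	0	0	0	0	-	-	-	-
Map1lc3a	2	LL	LL	LL	?	32	1	32	1	16	0	0	0	2	0	0	0	14	1	0	0	0	0	-	-	-	-
Ulk1	5	LL	SS	SS	LL	4	0	3	0	2	0	0	0	1	0	0	0	0	0	1	0	1	0	Np	-	-	-
Adipoq	16	LL	SS	LL	?	23	0	23	0	4	0	0	0	12	0	2	0	5	0	0	0	0	0	-	-	-	-
Casp3	8	LL	?	LL	LL	59	0	59	0	0	0	0	0	58	0	1	0	0	0	0	0	0	0	-	-	-	-
Csnk2a1	2	LL	?	LL	SS	1	0	1	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	-	-	-	-
Cxcl12	6	LL	SS	LL	SS	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	-	-	-	-
Fancc	13	SS	LL	LL	LS	23	0	23	0	1	0	0	0	22	0	0	0	0	0	0	0	0	0	-	-	-	-
Fzd2	11	SS	LL	?	SS	13	2	13	2	5	1	1	1	-	-	1	0	6	0	0	0	0	0	-	-	-	-
Mmp13	9	LL	SS	LL	LL	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	-	-	-	-
Runx2	17	SS	LL	SS	LL	578	15	578	15	0	0	0	0	578	15	0	0	0	0	0	0	0	0	-	-	-	-
Sox5	6	LL	LL	SS	LL	3226	115	3221	111	10	3	1	0	3175	104	21	4	14	0	5	4	5	0	Np	143,783,835	14	-
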