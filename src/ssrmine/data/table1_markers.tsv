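# Published 46-marker SSR panel for Boswellia papyrifera, with
# cross-amplification calls in B. pirrotae (br) and B. popoviana (bv).
# allele_count: alleles in 10 B. papyrifera genotypes; ho: observed
# heterozygosity over the same 10 genotypes; quality grades 1-3.
# Cross-species tokens: het, hom, het_out_of_range, no_ampl, not_tested.
# Primers exclude the M13 (AACAGGTATGACCATGA) and GTTT 5' tails used for
# fluorescent labelling; sizes in bp.
name	forward_primer	reverse_primer	motif	allele_count	size_min	size_max	quality	ho	br	bv
Bp01	TTGTTAAGGCTTTTCTCCTC	GTTGCTTATCTTTGGCTGAG	(AAG)6	4	119	134	2	0.34	het	hom
Bp02	TGAGAAGTTTACCCTTTATGTTT	TCTCTGCCTCTTCTTCTTATTT	(ATT)13	7	195	219	2	0.78	hom	hom
Bp03	ATGGGGAAAGGTTAAAGATC	CTGCACAACACAAGTTAAGC	(ATC)6	3	123	129	1	0.1	het	het
Bp04	TATCAACACTTTTGTTTTGC	CAATTCGAGTCTCCTCAAC	(TTC)8	2	182	197	3	0.2	het	het
Bp05	GGAGCAGGTACCTTGTATGT	AACAGATCTCTTGGTTTGATT	(AAC)7	5	232	250	1	0.8	hom	hom
Bp06	GATCTCCACTTGATCAGGAC	ACATGGAAAATTGAAAGCAC	(TTC)9	8	263	297	1	0.5	het	het
Bp07	GAAACTTTGTGGGTGTTTGT	TCATCCTCTGACATATCCATT	(ATT)8	3	284	293	1	0.34	hom	hom
Bp08	TTTTCTGTGTTTTGTACGCA	GCATGCAAGAAATAGGAGAG	(ATT)6	3	207	213	2	0.11	no_ampl	no_ampl
Bp09	TTGATCAATTATTTCGGACA	AAAATGCAAGTCCTTTGTAA	(ATT)11	7	292	331	1	0.78	no_ampl	het
Bp10	CTTTGGCAGATTCAAATAGG	GACACAAGAAAATTGAGGGA	(TTC)6	4	197	213	1	0.11	het	het
Bp11	AGAGAATTCCCTAAGGAGAGA	TCTACAATAGCCCAGCAACT	(TTC)9	6	284	307	1	0.78	hom	het
Bp12	ACCCATGATAAAGAGTTCCA	GAGAACGCCGTTTGAGTT	(ATT)10	7	238	302	2	0.56	het	no_ampl
Bp13	ATAATTTCCCACCAGGAGAT	CAACGAACTACAAGTATTGAATG	(ATT)7	3	227	239	1	0.22	hom	hom
Bp14	GGCAATTATTTGATCGCTAC	ATGACATTCATTCGTAACCC	(ATT)15	8	198	253	1	0.44	het	hom
Bp15	TATATGCCTTGCTAAGCGTT	AAACTCCGAGCTGACTACAC	(ATC)10	7	301	337	1	0.78	het	hom
Bp16	AAAACTTTGTTTCCTCTCCA	TCAGAAGGAAGCACTTCAAC	(TCC)11	2	218	221	1	0.33	hom	hom
Bp17	AGCAATATTTCCAAAGGACA	CTGCCCAATAACATAGTTCC	(TTC)11	6	200	215	1	0.4	no_ampl	hom
Bp18	TTATCTTGTAGTGGGATGGG	GAGAACTGGTAATCACATGAAA	(TTC)12	6	221	262	2	0.67	hom	no_ampl
Bp19	GTGCCAGAATTCAGGTATGT	GGTTGTGAGTCCACCATTAT	(TTC)13	5	287	321	2	0.1	het	hom
Bp20	TGCTTTATGACTTTGTTGAGA	GAACCATCATGCAATTAGTTT	(TTC)15	10	227	266	2	0.5	het	hom
Bp21	CAGAGTTAATAATATAAGTAGCAGCA	CTATGTTCATACTTAGAAAAGTTGG	(TTC)16	12	117	299	1	0.6	hom	hom
Bp22	TAAAACCATTTTCAGCAAGG	AGAACCAGACCTTCAAATCA	(TTC)17	11	237	307	1	0.7	hom	het
Bp23	GCGAATTTGCTCTGTAATTC	TAAGACCCCAAGAAATTGAA	(TTC)20	11	224	266	2	0.8	het	hom
Bp24	TATTTGTCAACAGATTGGGG	CAGTCTAAGTCCACAAACTCC	(CGGGG)3	2	241	251	1	0	hom	hom
Bp25	ATCATCATCAGGTGAAGACC	ATGTCGTTTTCGACTTTCG	(TCTCGC)3	4	261	279	1	0.22	hom	hom
Bp26	AAATCATGTTTGGCTAATGG	TGCAAATGCAAATTAATGG	(TGCC)6	3	235	247	1	0.34	hom	hom
Bp27	CTCTAGATGCATAGGGATGG	AAATATAATCCTAAACCTTGCG	(TCCGGG)3	2	240	246	1	0.25	no_ampl	no_ampl
Bp28	CAAATCCTTGTGATTTCTCC	AAGTAGCCATAAATAATCATAGGG	(AAGAG)3	4	262	272	1	0.14	het	hom
Bp29	ATTTCACAAATCACTTTCGC	TTAACAAGTAACGCTAACGC	(TC)10(AGCG)5	6	249	264	1	0.43	hom	het
Bp30	ATATGCTAGAGACTTGGCCC	TTTTCAATGCTTGGATGC	(TTGGGC)3	3	200	212	1	0.34	hom	hom
Bp31	CAGAACAAAAGTGACAGTTAGC	GAGGCAAAGAGACTTGACC	(AGAGC)4	4	277	307	2	0.75	hom	no_ampl
Bp32	TCATAACTTCCAAAATTGAGC	TTTCTATCTTTGGATCAATGC	(TCTG)4	3	144	156	1	0.11	hom	no_ampl
Bp33	CGTCTACCTCCTTCTCTTCC	GTACTAAACCCTCCGTTCG	(TCTCC)3	2	171	181	3	0.33	het	no_ampl
Bp34	AGAGAACATCCCAAGAATCC	AGGATGGAGAGCCCTAGC	(ATGGAG)4	4	183	193	1	0.56	het	not_tested
Bp35	GGCTCCTCGCTAACCGACC	CTCCCAGTCGAGATCGAGCC	(TTGGCG)4	2	224	230	1	0.1	hom	not_tested
Bp36	GGTATAAAGAGAAAGGGATAGAGG	CACAATTTACTGGCAATGG	(TGTGC)3	4	211	226	2	0.89	hom	not_tested
Bp37	ATCTCGCATTCCTACATCC	ACGACCTCTTCATCTAACCC	(ATGC)5	2	277	283	1	0.11	hom	not_tested
Bp38	GTTGAGAATGAGAAGAACGG	CATCAACTTCCTCAAATTCC	(ATC)7,(8)	5	243	273	1	0.22	het	not_tested
Bp39	TCATGGAATAAGAAACCAAA	TCTTAACATTTCGTCTGCTG	(ATC)8,(9)	8	247	298	2	0.6	het	not_tested
Bp40	AAACAAATATACGTGGCACA	TCCAAGTGAACATCCAAAAT	(ATT)8,(14)	3	240	255	2	0.3	hom	not_tested
Bp41	TGGGTTTAAAGTATTCTAAAAGG	CATTAGAAGAGGCAAAATGG	(ATT)8,(9)	4	230	252	2	0.22	hom	not_tested
Bp42	TTATAAGCAGAGCAAATTATAGC	CTAATTTCGCAATTTAAGGC	(ATT)10,(11)	6	228	264	2	0.4	hom	not_tested
Bp43	CCAAGCCTATACACTTCTTCA	GATGAATTGGGCTTAGATTG	(TTC)6,(8)	6	272	293	3	0.89	het	not_tested
Bp44	CCATATGGGGATATAGGTCA	TTGGCCAAGAAGAAACTTAG	(ATT)6,(7)	4	226	235	2	0.25	het_out_of_range	not_tested
Bp45	AACAGTTGGTTTAACAACGC	CTTAAAAGGGAACTGGAAGG	(AACAAG)3,(4)	3	281	293	1	0.67	het	not_tested
Bp46	ATATTCAATTTATCTGTGTGACG	TTTGATTTCAAAGGAAAACG	(ATATT)3,(4)	2	256	271	2	0.75	hom	not_tested
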