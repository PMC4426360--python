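contig	pos	contig_length	ref	alt	depth	ref_reads	alt_reads	other_reads	qual	n_aa	n_ab	n_bb	n_nn	neighbor_pos	rna_retained	rna_reason	rad_retained	rad_reason	flank_ok
ctg00	36	71	A	G	7	4	3	0	25.0	6	4	0	0	0	1		1		1
ctg01	35	71	A	G	7	4	3	0	25.0	6	4	0	0	0	1		1		0
ctg02	37	71	A	G	7	4	3	0	25.0	6	4	0	0	0	1		1		0
ctg03	100	200	A	G	6	3	3	0	40.0	5	5	0	0	0	0	depth	0	depth	1
ctg04	100	200	A	G	20	10	6	4	40.0	5	5	0	0	0	0	allele_ratio	1		1
ctg05	100	200	A	G	20	11	6	3	40.0	5	5	0	0	0	1		1		1
ctg06	100	200	A	G	15	8	7	0	24.9	5	5	0	0	0	1		0	quality	1
ctg07	100	200	A	G	15	8	7	0	25.0	5	5	0	0	0	1		1		1
ctg08	100	200	A	G	15	8	7	0	40.0	5	3	0	2	0	0	maf	1		1
ctg09	100	200	A	G	15	8	7	0	40.0	4	3	0	3	0	1		0	missingness	1
ctg10	100	200	A	G	0	0	0	0	40.0	5	5	0	0	0	0	no_coverage	0	depth	1
ctg11	100	200	A	G	15	8	7	0	40.0	7	3	0	0	0	0	maf	1		1
ctg12	100	200	A	G	15	8	7	0	40.0	6	4	0	0	0	1		1		1
ctg13	100	200	A	G	15	8	7	0	40.0	5	5	0	0	120	1		1		0
ctg14	100	200	A	G	15	8	7	0	40.0	5	5	0	0	135	1		1		0
ctg15	100	200	A	G	15	8	7	0	40.0	5	5	0	0	136	1		1		1
ctg16	100	200	A	G	15	8	7	0	40.0	5	5	0	0	64	1		1		1
ctg17	100	200	A	G	15	8	7	0	40.0	5	5	0	0	65	1		1		0
ctg18	250	500	A	G	0	0	0	0	25.0	4	3	1	2	320	0	no_coverage	0	depth	1
ctg19	250	500	A	G	30	14	10	6	25.0	0	9	0	1	0	0	allele_ratio	1		1
ctg20	250	500	A	G	8	6	2	0	10.0	5	5	0	0	0	1		0	quality	1
ctg21	250	500	A	G	0	0	0	0	30.0	5	1	2	2	280	0	no_coverage	0	depth	0
ctg22	250	500	A	G	7	5	1	1	10.0	6	1	0	3	0	0	maf	0	quality	1
ctg23	250	500	A	G	30	26	4	0	60.0	5	0	2	3	290	1		0	missingness	1
ctg24	250	500	A	G	6	4	2	0	10.0	2	4	0	4	290	0	depth	0	depth	1
ctg25	250	500	A	G	5	3	0	2	30.0	4	0	4	2	280	0	depth	0	depth	0
ctg26	250	500	A	G	5	4	0	1	60.0	2	3	1	4	290	0	depth	0	depth	1
ctg27	250	500	A	G	20	13	7	0	25.0	2	4	0	4	280	1		0	missingness	0
ctg28	250	500	A	G	30	9	15	6	10.0	3	3	0	4	320	0	allele_ratio	0	quality	1
ctg29	250	500	A	G	6	3	3	0	25.0	5	2	0	3	0	0	depth	0	depth	1
ctg30	250	500	A	G	0	0	0	0	10.0	3	2	2	3	280	0	no_coverage	0	depth	0
ctg31	250	500	A	G	30	5	19	6	60.0	3	3	2	2	0	0	allele_ratio	1		1
ctg32	250	500	A	G	30	5	19	6	10.0	4	5	0	1	0	0	allele_ratio	0	quality	1
ctg33	250	500	A	G	12	5	7	0	30.0	7	1	0	2	280	0	maf	1		0
ctg34	250	500	A	G	12	6	4	2	60.0	1	7	0	2	0	0	allele_ratio	1		1
ctg35	250	500	A	G	8	5	3	0	25.0	3	1	2	4	280	1		0	missingness	0
ctg36	250	500	A	G	8	6	0	2	60.0	3	1	2	4	280	0	allele_ratio	0	missingness	0
ctg37	250	500	A	G	7	0	6	1	25.0	7	1	2	0	0	1		1		1
ctg38	250	500	A	G	8	1	5	2	24.9	4	2	0	4	320	0	maf	0	quality	1
ctg39	250	500	A	G	12	9	2	1	24.9	4	5	0	1	0	1		0	quality	1
ctg40	250	500	A	G	30	1	29	0	60.0	4	4	2	0	290	1		1		1
ctg41	250	500	A	G	0	0	0	0	60.0	3	2	1	4	0	0	no_coverage	0	depth	1
ctg42	250	500	A	G	5	0	4	1	30.0	10	0	0	0	280	0	depth	0	depth	0
ctg43	250	500	A	G	20	13	5	2	60.0	6	0	2	2	320	1		1		1
ctg44	250	500	A	G	5	1	3	1	24.9	4	1	3	2	320	0	depth	0	depth	1
ctg45	250	500	A	G	8	5	1	2	60.0	1	6	0	3	320	0	allele_ratio	0	missingness	1
ctg46	250	500	A	G	8	2	5	1	25.0	1	7	0	2	0	1		1		1
ctg47	250	500	A	G	8	1	6	1	24.9	0	8	0	2	0	1		0	quality	1
ctg48	250	500	A	G	12	5	7	0	60.0	1	8	0	1	0	1		1		1
ctg49	250	500	A	G	30	3	25	2	30.0	1	8	0	1	290	1		1		1
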