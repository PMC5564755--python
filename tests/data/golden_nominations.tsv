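gene_pair	gene5	gene3	chrom5	chrom3	strand5	strand3	distance_bp	read_through	junction_at_splice_site	in_frame	n_tumor_positive	n_benign_positive	fisher_p	fisher_q	wilcoxon_p	mean_rpkm_tumor	var_rpkm_tumor	mean_rpkm_benign	var_rpkm_benign
RT1_5P-RT1_3P	RT1_5P	RT1_3P	ctgRT1	ctgRT1	+	+	1000	Y	Y	Y	7	0	2.3E-03	3.4E-03	*	0.686	0.09121	0	*
RT2_5P-RT2_3P	RT2_5P	RT2_3P	ctgRT2	ctgRT2	+	+	1000	Y	Y	N	10	0	3.4E-05	1.0E-04	*	0.6189	0.05529	0	*
RT3_5P-RT3_3P	RT3_5P	RT3_3P	ctgRT3	ctgRT3	+	+	1000	Y	Y	N	6	0	6.9E-03	6.9E-03	*	0.7194	0.04539	0	*
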