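gene_pair	n_tumor_positive	n_benign_positive	n_tumor	n_benign	printed_fisher_p	reproducible
TMPRSS2-ERG	19	0	44	44	1.6E-06	N
KLK4-KLK3	17	5	44	44	3.0E-03	Y
DNAJB1-TECR	31	8	44	44	6.7E-07	Y
SMG5-TMEM79	20	6	44	44	1.0E-03	Y
GOLM1-NAA35	42	30	44	44	8.2E-04	Y
SMG5-PAQR6	11	1	44	44	1.7E-03	Y
C9orf163-SEC16A	34	11	44	44	8.2E-07	Y
SLC45A3-ELK4	14	5	44	44	1.8E-02	Y
PXDN-AC144450.2	27	1	44	44	4.2E-10	Y
ACER3-B3GNT6	19	1	44	44	2.1E-06	Y
DSCC1-KB_1471A8.1	6	0	44	44	1.3E-02	Y
ACSS1-APMAP	29	20	44	44	4.3E-02	Y
SPON2-CTBP1	14	2	44	44	8.2E-04	Y
SSBP2-CPNE4	16	1	44	44	3.1E-05	Y
NSUN4-FAAH	6	0	44	44	1.3E-02	Y
TMEM219-TAOK2	10	2	44	44	2.5E-02	N
RP11_321F6.1-SMAD6	5	0	44	44	2.8E-02	Y
ZNF841-ZNF432	15	5	44	44	1.0E-02	Y
ZNF551-ZNF776	9	1	44	44	7.4E-03	N
RP11_17A19.1-KCTD1	25	6	44	44	2.0E-05	Y
FAM83H-RP11_429J17.6	15	0	44	44	1.4E-04	N
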