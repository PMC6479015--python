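genus	ETR	ETU	GBR	GBU	GN	KE	PE	SP	SW	USC	USW
Streptococcus	15.3	25.9	29.5	26.0	8.7	31.5	49.6	36.5	29.5	25.7	26.5
Staphylococcus	21.5	34.2	17.5	20.5	20.6	27.7	29.6	27.3	40.7	26.0	30.4
Corynebacterium 1	11.0	8.8	4.8	5.5	1.8	4.8	4.2	2.5	3.9	3.2	4.1
Propionibacterium	3.0	4.4	3.8	3.6	2.0	5.8	4.1	4.3	6.6	3.7	5.6
Rhizobium	22.5	1.3	1.5	1.5	1.2	1.2	1.3	1.4	1.2	1.4	1.4
Lactobacillus	7.0	4.7	4.3	4.3	8.3	6.7	4.1	4.1	4.3	3.7	3.8
Dyella	0.9	1.8	3.6	3.6	1.2	2.9	2.7	2.6	2.0	1.3	6.4
Rothia	1.7	3.0	3.5	3.1	1.3	2.4	3.3	3.1	2.0	2.1	2.9
Kocuria	4.4	3.3	1.6	2.3	1.1	2.2	1.2	1.2	1.1	1.0	1.1
Veillonella	2.0	1.2	1.1	1.1	1.3	1.6	2.8	1.4	1.7	1.8	1.3
Bifidobacterium	2.5	2.4	1.6	1.3	1.4	1.3	1.0	1.0	1.0	0.8	0.9
Acinetobacter	3.3	1.7	1.6	1.5	1.0	2.0	1.4	1.6	1.2	1.3	1.2
Klebsiella	2.2	2.1	2.1	2.2	7.0	2.3	2.1	2.1	2.2	2.3	2.2
Gemella	1.5	1.4	1.4	1.4	1.1	1.6	2.8	2.0	2.9	1.7	1.6
Achromobacter	8.1	0.3	0.3	0.3	0.3	0.3	0.3	0.3	0.3	0.3	0.3
Escherichia/Shigella	1.2	0.9	0.9	0.9	1.8	1.0	0.9	1.0	1.0	1.3	1.0
Bacillus	0.9	1.2	2.4	1.5	0.8	1.0	0.8	0.8	0.9	0.8	0.8
Stenotrophomonas	0.9	0.6	0.7	0.8	0.6	0.6	0.7	0.9	0.7	0.8	1.1
Enterococcus	1.1	0.8	0.8	0.9	1.7	0.8	0.8	0.9	0.9	0.8	0.9
Janthinobacterium	0.3	0.5	0.6	0.8	0.4	0.6	0.5	0.6	0.7	0.5	1.1
Anaerococcus	1.1	0.7	0.5	0.5	0.4	0.6	0.6	0.4	0.5	0.4	0.4
Acidocella	0.2	0.3	0.6	0.4	0.3	0.5	0.4	0.5	0.7	0.3	1.0
Enterobacter	0.4	0.4	0.4	0.4	0.4	0.5	0.4	0.5	0.4	0.5	0.6
Bacteroides	0.3	0.3	0.3	0.3	0.6	0.4	0.3	0.3	0.4	0.3	0.3
Pseudomonas	0.3	0.3	0.3	0.3	0.2	0.3	0.4	0.3	0.3	0.4	0.4
Chryseobacterium	0.5	0.3	0.3	0.3	0.3	0.4	0.3	0.3	0.3	0.3	0.3
Tatumella	0.7	0.7	0.7	0.7	0.8	0.7	0.8	0.7	0.7	0.7	0.7
Psychrobacter	0.8	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2
Clostridium sensu stricto 18	0.1	0.1	0.1	0.2	0.2	0.1	0.1	0.1	0.1	0.1	0.2
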