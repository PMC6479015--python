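genus	ETR	ETU	GBR	GBU	GN	KE	PE	SP	SW	USC	USW
Streptococcus	18.2	16.0	27.7	33.6	12.3	16.5	15.7	12.5	9.0	7.1	12.1
Escherichia/Shigella	19.0	22.0	13.5	13.6	17.5	19.0	19.9	16.7	12.0	9.2	10.0
Veillonella	13.7	9.8	13.2	11.9	5.6	14.3	14.3	13.6	10.9	12.4	9.6
Bifidobacterium	8.7	10.5	15.1	16.0	19.9	9.9	9.3	11.7	9.5	5.6	10.2
Bacteroides	9.6	9.4	7.7	7.3	9.6	8.8	10.8	12.0	15.2	13.4	18.1
Lactobacillus	15.2	10.6	14.7	9.3	12.8	12.5	5.8	5.1	4.6	4.5	5.6
Clostridium sensu stricto 1	3.2	3.0	2.8	2.5	3.0	2.8	3.0	3.7	6.1	5.9	4.1
Lachnoclostridium	2.4	2.7	2.2	2.4	2.3	2.9	3.3	2.7	2.8	2.1	3.8
Klebsiella	1.8	2.6	2.3	3.4	2.7	2.5	3.3	2.2	2.7	2.8	1.9
Parabacteroides	2.1	2.3	2.1	2.1	2.1	2.0	2.0	2.4	3.6	2.4	2.1
Enterococcus	1.4	1.2	1.2	1.5	3.1	1.1	1.3	1.5	1.3	1.0	1.4
Enterobacter	1.1	1.1	1.1	1.1	1.1	1.2	1.3	1.7	1.6	1.8	1.8
Megasphaera	1.0	1.0	1.0	1.3	0.9	1.5	1.1	0.9	1.0	0.9	1.0
Staphylococcus	0.7	0.7	0.9	1.1	0.7	0.6	0.8	0.7	0.9	0.8	0.8
Prevotella 9	0.8	0.9	0.9	0.9	0.8	1.1	0.9	0.8	0.8	0.8	0.8
Erysipelatoclostridium	0.6	0.7	0.6	0.6	0.7	0.6	0.8	0.6	0.7	0.6	0.8
Rothia	0.4	0.5	0.8	0.8	0.4	0.6	0.5	0.6	0.4	0.4	0.4
Citrobacter	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.6
Akkermansia	0.5	0.6	0.5	0.5	0.5	0.5	0.5	0.6	0.5	0.5	0.5
Campylobacter	0.8	0.8	0.8	0.8	0.8	0.8	0.7	0.7	0.7	0.7	0.9
Lactococcus	0.5	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4
Gemella	0.3	0.3	0.5	0.5	0.2	0.3	0.3	0.3	0.3	0.3	0.3
Tyzzerella 4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4
Blautia	0.3	0.4	0.3	0.3	0.3	0.3	0.4	0.3	0.4	0.3	0.4
Paucisalibacillus	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5	0.5
Leuconostoc	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2
Acinetobacter	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2	0.2
Acetobacter	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1
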