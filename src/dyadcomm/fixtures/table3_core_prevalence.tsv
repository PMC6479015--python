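niche	genus	ETR	ETU	GBR	GBU	GN	KE	PE	SP	SW	USC	USW	Overall
feces	Streptococcus	100.0	96.9	100.0	100.0	100.0	100.0	100.0	97.3	95.7	83.3	97.6	98.4
feces	Escherichia/Shigella	100.0	96.9	89.5	86.8	96.9	95.2	97.6	86.5	91.3	75.0	80.5	91.7
feces	Veillonella	95.0	84.4	94.7	94.7	75.0	90.5	92.9	94.6	87.0	91.7	87.8	90.2
feces	Bifidobacterium	80.0	81.3	92.1	97.4	100.0	85.7	85.7	89.2	82.6	50.0	87.8	87.0
feces	Lactobacillus	92.5	87.5	97.4	86.8	90.6	92.9	64.3	48.6	47.8	41.7	61.0	76.7
feces	Bacteroides	70.0	53.1	47.4	42.1	75.0	54.8	69.0	70.3	87.0	75.0	95.1	66.0
milk	Staphylococcus	100.0	100.0	92.3	97.4	100.0	100.0	100.0	100.0	100.0	100.0	100.0	98.7
milk	Streptococcus	100.0	100.0	100.0	97.4	81.6	100.0	100.0	100.0	100.0	100.0	97.4	97.7
milk	Propionibacterium	75.0	82.4	74.4	68.4	31.6	90.5	79.1	82.5	87.5	78.9	84.6	75.5
milk	Corynebacterium 1	95.0	94.1	82.1	84.2	21.1	83.3	81.4	52.5	75.0	68.4	71.8	73.7
milk	Dyella	7.5	64.7	84.6	84.2	34.2	83.3	86.0	80.0	62.5	42.1	94.9	67.4
milk	Acinetobacter	92.5	61.8	56.4	47.4	7.9	73.8	44.2	55.0	29.2	36.8	30.8	50.3
milk	Kocuria	92.5	76.5	43.6	65.8	10.5	69.0	18.6	17.5	12.5	0.0	12.8	40.7
milk	Rhizobium	100.0	11.8	30.8	28.9	31.1	4.8	14.0	25.0	4.2	21.1	20.5	25.5
milk	Brevundimonas	100.0	11.8	2.6	13.2	2.6	16.7	7.0	15.0	8.3	15.8	15.4	19.7
milk	Achromobacter	100.0	2.9	5.1	2.6	2.6	0.0	2.3	0.0	0.0	5.3	5.1	12.4
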