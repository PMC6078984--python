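gene	chrom	start	end	strand
MUC1	1	401	1600	+
TP53	1	2001	2900	+
GATA3	1	3301	4200	+
MUC2	1	4601	5800	+
MUC3A	1	6201	7400	+
MUC4	1	7801	9000	+
AKT1	1	9401	10300	+
MSH2	2	401	1300	+
MSH6	2	1701	2600	+
MUC5AC	2	3001	4200	+
MUC5B	2	4601	5800	+
MUC6	2	6201	7400	+
PIK3CA	2	7801	8700	+
MUC12	3	401	1600	+
MUC13	3	2001	3200	+
MUC16	3	3601	4800	+
MUC17	3	5201	6400	+
MUC20	3	6801	8000	+
CDH1	3	8401	9300	+
MAP3K1	3	9701	10600	+
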