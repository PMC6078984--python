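chrom	arm	start	end
1	1p	1	5350
1	1q	5351	10700
2	2p	1	4550
2	2q	4551	9100
3	3p	1	5500
3	3q	5501	11000
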