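contig	strand	intron_start	intron_end	count
chrF	+	1020	2000	1
chrF	+	2200	3000	2
chrF	+	2195	3000	1
chrF	+	8100	9000	3
chrF	+	8108	9000	1
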