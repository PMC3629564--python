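chrF	fixture	exon	101	400	.	+	.	gene_id "m1"; transcript_id "t1";
chrF	fixture	exon	1001	1020	.	+	.	gene_id "m2"; transcript_id "t2";
chrF	fixture	exon	2001	2200	.	+	.	gene_id "m2"; transcript_id "t2";
chrF	fixture	exon	3001	3100	.	+	.	gene_id "m2"; transcript_id "t2";
chrF	fixture	exon	5001	16000	.	+	.	gene_id "m3"; transcript_id "t3";
chrF	fixture	exon	17001	17200	.	+	.	gene_id "m3"; transcript_id "t3";
chrF	fixture	exon	2006	2195	.	+	.	gene_id "m4"; transcript_id "t4";
chrF	fixture	exon	3001	3100	.	+	.	gene_id "m4"; transcript_id "t4";
chrF	fixture	exon	8001	8100	.	+	.	gene_id "m5"; transcript_id "t5";
chrF	fixture	exon	9001	9150	.	+	.	gene_id "m5"; transcript_id "t5";
chrF	fixture	exon	8006	8108	.	+	.	gene_id "m6"; transcript_id "t6";
chrF	fixture	exon	9001	9150	.	+	.	gene_id "m6"; transcript_id "t6";
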