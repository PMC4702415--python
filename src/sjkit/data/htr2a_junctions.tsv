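# Published splice-junction table for human HTR2A (reverse strand), summed across 211 prefrontal-cortex samples.
# from_exon/to_exon are in transcription order; alternatives sharing one splice boundary are printed as "x or y"
# (the first label is used when collapsing to variant groups).
from_exon	to_exon	total_reads	n_samples
0	2	28	21
0	2tr	1	1
0	3	126	73
0	4	1	1
1 or 1ext	2	15802	205
1 or 1ext	2tr	45	39
1 or 1ext	3	16	14
1 or 1ext	3b	1	1
2 or 1int	3	15253	200
2 or 1int	3b	1	1
3	3a	72	54
3	3b	39	34
3	4 or 4ext	14221	203
3a	3b	26	19
3a	4 or 4ext	108	60
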