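# Published exon catalogue for the human serotonin receptor 2A gene (HTR2A), reverse strand of chr13, hg19/GRCh37 coordinates (1-based inclusive).
# printed_size_bp is the size as printed in the source table; rows 2 and 2tr carry printed sizes (740/196) that are swapped
# relative to their printed coordinate spans (196/740) -- the coordinates are taken as authoritative (printed_as flag marks the clash).
exon	printed_size_bp	chrom	start	end	strand	variant_group	printed_as_consistent	notes
0	187	chr13	47472087	47472273	-	0	yes	newly described
1ext	1465	chr13	47470809	47472273	-	1	yes	extended 5' UTR variant
1int	2644	chr13	47469630	47472273	-	1	yes	intron-1 retention variant
1	403	chr13	47470809	47471211	-	1	yes	annotated
2	740	chr13	47469630	47469825	-	2	no	annotated; printed size mismatches coordinate span (196)
2tr	196	chr13	47469630	47470369	-	2	no	truncating alternative acceptor; printed size mismatches coordinate span (740)
3	201	chr13	47466525	47466725	-	3	yes	annotated
3a	118	chr13	47458674	47458791	-	3a	yes	previously described rare exon
3b	1175	chr13	47456022	47457197	-	3b	yes	newly described; likely terminal
4	4098	chr13	47405677	47409774	-	4	yes	annotated; canonical poly-A at chr13:47405698-47405703
4ext	9716	chr13	47400058	47409774	-	4	yes	extended 3' UTR to poly-A cluster chr13:47400058-47400144
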