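# Published exon catalogue for HTR2A-AS1 (antisense long non-coding RNA), forward strand of chr13, hg19/GRCh37 (1-based inclusive).
# Exons flagged size_estimated have no 5' junction read; their size was estimated from local read depth.
# tss_score: promoter-prediction score carried as optional annotation (empty where not reported).
exon	size_bp	chrom	start	end	strand	variant_group	size_estimated	tss_predicted	tss_score	notes
1	71	chr13	47370678	47370748	+	1	yes	chr13:47370715-47370719	0.897
2	82	chr13	47426280	47426361	+	2	yes	chr13:47426295-47426299	0.5747	annotated
3	316	chr13	47428074	47428389	+	3	no		 	annotated; no junction reads observed
3.1	144	chr13	47428074	47428217	+	3	no
4	139	chr13	47429408	47429546	+	4	yes	chr13:47429250-47429253	0.2663
5	117	chr13	47429726	47429842	+	5	yes	chr13:47429797-47429804	0.5568
6	210	chr13	47430225	47430434	+	6	no		 	annotated; no junction reads observed
7	133	chr13	47466546	47466678	+	7	no		 	overlaps HTR2A exon 3
7.1	194	chr13	47466546	47466739	+	7	no		 	overlaps HTR2A exon 3
8	101	chr13	47469779	47469879	+	8	yes	chr13:47469614-47469622	0.7864	overlaps HTR2A exon 2
9	167	chr13	47471212	47471378	+	9	yes	chr13:47471046-47471066	0.9737	overlaps HTR2A exon 1ext
9.1	101	chr13	47471282	47471382	+	9	no		 	overlaps HTR2A exon 1ext
10	101	chr13	47472971	47473071	+	10	yes	chr13:47473021-47473029	0.7151
11	101	chr13	47474379	47474479	+	11	yes	chr13:47474236-47474243	0.7058
12	101	chr13	47476850	47476950	+	12	yes	chr13:47476912-47476920	0.7333
13	58	chr13	47566052	47566109	+	13	no
14	46	chr13	47595782	47595827	+	14	no
15	59	chr13	47660942	47661000	+	15	no
16	29	chr13	47748905	47748933	+	16	no
17	123	chr13	47791699	47791821	+	17	no
17.1	119	chr13	47791703	47791821	+	17	no
18	69	chr13	47844316	47844384	+	18	no		 	contains canonical poly-A signal
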