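# Published per-sample allelic read counts at rs6313 for the 9 of 109 heterozygous prefrontal-cortex samples
# with significant allelic expression imbalance (exact one-sided binomial, Bonferroni x109, corrected alpha 0.05).
# printed_p / printed_p_corrected are the values as printed (3 significant figures).
sample	diagnosis	count_g	count_a	printed_p	printed_p_corrected
1	Scz	92	36	3.94e-07	4.30e-05
2	Scz	79	31	2.67e-06	2.91e-04
3	Control	143	78	7.31e-06	7.96e-04
4	Scz	95	48	5.25e-05	5.72e-03
5	Scz	46	16	8.82e-05	9.61e-03
6	Scz	67	30	1.09e-04	1.19e-02
7	Control	69	32	1.48e-04	1.61e-02
8	Control	57	26	4.39e-04	4.78e-02
9	Scz	78	41	4.44e-04	4.84e-02
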