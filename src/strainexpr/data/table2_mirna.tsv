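# Published heritability/correlation table for 6 miRNAs (typed verbatim).
# H2_results_pct is the unrounded heritability percentage quoted in the
# results prose (the printed table rounds H2 to 2 decimals); the printed CI
# column reproduces from these values, not from the rounded ones.
gene	Vb	Vw	Vt	H2	H2_results_pct	ci95	p_strain	r_ear	p_ear	r_cart	p_cart
miR-17	0.41	0.08	0.49	0.84	83.9	0.990	<0.001	0.083	0.422	-0.128	0.382
miR-27b-3p	0.49	0.28	0.77	0.64	64.0	0.926	0.001	0.258	0.276	-0.288	0.253
miR-140-5p	0.62	0.41	1.03	0.6	60.0	0.906	0.002	0.016	0.485	-0.169	0.347
miR-146b-5p	0.37	0.09	0.45	0.8	80.4	0.983	<0.001	0.197	0.324	-0.148	0.364
miR-224	0.41	0.09	0.5	0.82	81.8	0.986	<0.001	-0.013	0.487	-0.147	0.366
miR-675	0.3	0.18	0.48	0.63	62.5	0.918	0.001	0.601	0.096	-0.580	0.102
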