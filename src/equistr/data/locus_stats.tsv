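# Published per-locus genetic summaries for the 17-plex panel + amel.
# ho/he: observed/expected heterozygosity across all breeds; he_sw: an SW-score-based
# He prediction (stored, not modeled); pe1/pe2: per-locus parentage statistics printed
# as "PE1"/"PE2" (first parent / second parent; see docs/methods.md for the convention
# linking these columns to the published combined row); pi/pisib: probability of identity
# (unrelated / full sibs). ND = not determined, NA = not applicable.
marker	ho	he	he_sw	pe1	pe2	pi	pisib	unit_len
amel	0.56	0.68	NA	NA	NA	NA	NA	2
Eca28	0.80	0.79	0.71	0.579	0.401	ND	ND	4
Eca15	0.75	0.80	0.74	0.442	0.281	0.06	0.36	4
Eca07	0.64	0.75	0.71	0.639	0.461	0.12	0.42	4
Eca05	0.59	0.73	0.72	0.675	0.498	0.16	0.46	5
Eca12	0.56	0.69	0.75	0.726	0.561	0.18	0.47	4
Eca24	0.79	0.74	0.72	0.631	0.452	0.12	0.42	5
Eca22	0.60	0.74	0.73	0.591	0.411	0.14	0.45	4
Eca21	0.53	0.62	0.74	0.768	0.595	0.27	0.56	4
Eca25	0.55	0.62	0.74	0.791	0.650	0.31	0.56	4
Eca27	0.60	0.65	0.74	0.764	0.608	0.24	0.51	4
Eca14	0.63	0.63	0.61	0.771	0.607	0.23	0.51	4
Eca04a	0.68	0.73	0.75	0.668	0.488	0.13	0.44	4
Eca04b	0.69	0.74	0.66	0.664	0.488	0.14	0.44	5
Eca02	0.69	0.77	0.75	0.589	0.412	0.12	0.41	4
Eca03	0.66	0.75	0.73	0.657	0.481	0.13	0.42	4
Eca01	0.63	0.69	0.75	0.662	0.475	0.14	0.44	4
Eca20	0.89	0.86	0.75	0.426	0.270	0.03	0.32	4
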