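# Structural features and common-growth ranking of the 16 Mdng ORFs:
# peptide length (aa), mean intrinsic disorder score (IDS, flDPnn; ingested,
# never computed here), the published foldability label (low when IDS > 0.4,
# high when IDS < 0.1, intermediate otherwise), and the rank in the pooled
# common-growth experiment (1 = largest relative increase start -> cycle 5;
# n.a. for the two clones that failed to grow).
mdng	length_aa	ids	foldability	rank
Mdng1	147	0.51	low	2
Mdng2	167	0.48	low	n.a.
Mdng3	157	0.08	high	5
Mdng4	122	0.06	high	4
Mdng5	111	0.43	low	7
Mdng6	48	0.50	low	10
Mdng7	143	0.19	intermediate	n.a.
Mdng9	133	0.23	intermediate	6
Mdng10	155	0.17	intermediate	11
Mdng11	91	0.06	high	12
Mdng12	155	0.24	intermediate	9
Mdng13	101	0.11	intermediate	14
Mdng14	101	0.63	low	13
Mdng15	102	0.28	intermediate	1
Mdng16	70	0.18	intermediate	3
Mdng21	115	0.09	high	8
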