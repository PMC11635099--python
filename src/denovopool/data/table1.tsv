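# Per-gene transcriptomic response of the 16 mouse de novo gene (Mdng) expression
# clones: expression level of the mouse transcript relative to the hygromycin
# resistance transcript from the same vector, number of human genes with
# |fold change| > 2 and adjusted p < 0.05, and the top enriched GO term
# (pass-through annotation; GO analysis is external to this package).
mdng	expression	n_de	top_go
Mdng1	0.94	300	GO:0061792 secretory granule maturation
Mdng2	0.36	520	GO:0043269 regulation of ion transport
Mdng3	0.39	1044	GO:0031620 regulation of fever generation
Mdng4	0.04	77	GO:0010984 regulation of lipoprotein particle clearance
Mdng5	0.25	266	GO:0007155 cell adhesion
Mdng6	0.15	126	GO:0007155 cell adhesion
Mdng7	0.52	35	none
Mdng9	0.16	188	GO:0003308 negative regulation of Wnt signaling pathway involved in heart development
Mdng10	0.35	108	GO:0006700 C21-steroid hormone biosynthetic process
Mdng11	0.02	405	GO:0007156 homophilic cell adhesion via plasma membrane adhesion molecules
Mdng12	0.25	118	GO:0042662 negative regulation of mesodermal cell fate specification
Mdng13	0.07	1171	GO:0030198 extracellular matrix organization
Mdng14	0.17	744	GO:0071805 potassium ion transmembrane transport
Mdng15	0.63	393	GO:0006873 cellular ion homeostasis
Mdng16	0.15	2392	GO:0006700 C21-steroid hormone biosynthetic process
Mdng21	0.07	1165	GO:0009097 isoleucine biosynthetic process
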