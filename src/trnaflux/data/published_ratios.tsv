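# Differential nucleocytoplasmic distribution of tRNA isodecoders after
# exporter knockdown: published ratio = (N/C knockdown) / (N/C control).
trna_id	ratio
tRNA-Thr-AGT-3-1	2.042221128
tRNA-Ala-AGC-10-1	1.999167172
tRNA-Glu-TTC-1-1	1.658461909
tRNA-Arg-CCT-1-1	1.524281421
tRNA-Glu-TTC-2-1	1.480488632
tRNA-Cys-GCA-5-1	1.477380601
tRNA-Ile-AAT-3-1	1.455185042
tRNA-Val-CAC-5-1	1.378688966
tRNA-Ser-AGA-5-1	1.322156666
tRNA-Cys-GCA-1-1	1.304067958
tRNA-Leu-TAG-3-1	1.258855669
tRNA-Leu-TAA-2-1	1.209773187
tRNA-Lys-CTT-2-1	1.19750431
tRNA-Gly-CCC-1-1	1.145757275
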