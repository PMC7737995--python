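haplotype	Aksu	Bayatbadem	Demre	Firm	Geyikbayir	Kumluca	Phaselis	Termessos
H1	0	3	0	0	0	0	0	0
H2	0	0	0	0	0	0	6	0
H3	0	0	0	0	6	0	0	0
H4	0	0	0	0	0	0	0	4
H5	0	0	0	2	0	0	0	0
H6	0	0	0	2	0	0	0	0
H7	0	0	0	0	0	0	0	11
H8	0	0	0	0	0	3	0	0
H9	0	0	0	0	3	0	0	0
H10	0	0	2	0	0	0	0	0
H11	7	6	13	4	6	12	7	0
H12	2	0	0	0	0	0	0	0
H13	4	0	0	0	0	0	0	0
H14	1	0	0	0	0	0	0	0
H15	1	0	0	2	0	0	0	0
H16	0	0	0	1	0	0	0	0
H17	0	6	0	0	0	0	0	0
H18	0	0	0	0	0	0	2	0
H19	0	0	0	2	0	0	0	0
H20	0	0	0	2	0	0	0	0
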