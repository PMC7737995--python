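	H1	H2	H3	H4	H5	H6	H7	H8	H9	H10	H11	H12	H13	H14	H15	H16	H17	H18	H19
H2	8
H3	11	3
H4	8	4	5
H5	17	21	24	19
H6	16	22	21	22	19
H7	14	20	19	20	19	4
H8	11	19	22	17	14	7	5
H9	10	18	21	16	15	8	4	3
H10	11	19	22	17	17	8	4	3	2
H11	11	19	22	17	16	7	3	2	1	1
H12	24	22	19	24	31	12	14	19	18	18	17
H13	27	25	22	27	34	15	17	22	21	21	20	5
H14	26	22	19	24	35	20	22	27	26	26	25	8	5
H15	23	21	18	23	30	11	13	18	17	17	16	1	6	9
H16	22	20	17	22	29	12	12	17	16	16	15	2	7	10	1
H17	17	15	12	17	32	21	19	22	21	22	22	11	12	13	12	11
H18	17	15	12	17	32	21	19	22	23	22	22	11	12	11	12	11	2
H19	18	14	13	16	23	12	16	17	20	20	19	12	15	12	11	12	17	15
H20	16	16	15	16	21	8	12	15	16	16	15	10	13	14	9	10	17	15	4
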