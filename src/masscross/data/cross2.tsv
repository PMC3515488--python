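dam	S1	S2	S3	S4	S5	S6	S7	S8	S9	S10
D1	0	0	0	0	0	0	0	0	0	0
D2	0	16	0	14	9	29	0	5	3	2
D3	0	0	8	0	0	0	0	7	0	3
D4	0	8	4	0	3	0	19	1	0	1
D5	0	1	3	37	0	2	0	3	0	0
D6	0	0	2	10	24	0	0	0	0	0
D7	0	6	28	2	5	26	1	0	0	0
D8	0	0	0	5	0	0	22	0	3	112
D9	0	6	0	10	0	0	0	0	0	0
D10	0	38	4	16	0	1	1	54	0	0
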