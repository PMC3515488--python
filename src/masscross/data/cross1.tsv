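dam	S1	S2	S3	S4	S5	S6	S7	S8	S9	S10
D1	1	0	1	0	7	0	0	0	0	4
D2	0	0	6	1	6	0	0	8	0	0
D3	0	52	155	23	6	36	3	0	0	5
D4	0	104	11	1	1	2	0	2	0	0
D5	14	3	2	0	42	8	0	3	28	10
D6	37	14	0	4	1	34	0	0	1	15
D7	0	0	0	0	0	0	0	0	0	0
D8	0	0	0	0	1	1	0	0	0	0
D9	1	0	0	1	0	1	0	0	0	1
D10	2	64	3	20	4	10	1	16	1	6
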