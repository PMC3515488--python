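dam	S1	S2	S3	S4	S5	S6	S7	S8	S9	S10
D1	0	0	0	0	0	0	0	0	0	0
D2	90	2	123	126	205	0	0	14	0	0
D3	0	0	0	0	0	0	0	0	0	0
D4	0	0	0	0	0	0	0	0	0	0
D5	0	0	0	0	0	0	0	0	0	0
D6	2	0	0	0	0	0	0	0	0	0
D7	0	0	0	0	1	0	0	0	0	0
D8	0	0	0	0	0	0	0	0	0	0
D9	0	0	0	0	0	0	0	0	0	0
D10	0	0	0	0	0	0	0	0	0	0
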