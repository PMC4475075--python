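R1	-1/2	1/2	-1/2	1/2	1	1/2
R2	-1	-1	1	1	0	1
R3	1	0	0	0	0	0
R4	0	0	0	1	1/2	1/2
R5	0	0	0	0	0	1
R6	0	0	0	0	1	0
R7f	0	1	0	0	0	0
R7b	0	0	1	0	0	0
R8	0	0	0	1	0	0
R9	0	0	0	0	1/2	1/2
R10	0	0	0	0	1	0
R11	0	0	0	0	0	1
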