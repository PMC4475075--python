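#	R1	R2	R3	R4	R5	R6	R7r	R8	R9	R10	R11
#rev	0	0	0	0	0	0	1	0	0	0	0
MA	-2	-1	-2	2	1	1	0	0	0	0	0
MB	-2	-3	-4	4	2	0	-2	0	0	0	0
MC	2	1	2	-4	0	0	0	2	0	0	0
MD	-2	-1	-2	2	0	0	0	0	2	0	0
ME	-2	-1	-2	2	1	0	0	0	0	1	0
MF	0	0	0	0	-1	0	0	0	0	0	1
MG	-4	-4	-6	6	3	1	-2	0	0	0	0
MH	0	-2	-2	0	2	0	-2	2	0	0	0
MI	0	0	0	-2	0	0	0	2	2	0	0
MJ	-4	-2	-4	4	1	0	0	0	2	1	0
MK	-2	-1	-2	2	0	0	0	0	0	1	1
ML	-2	-1	-2	2	0	1	0	0	0	0	1
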