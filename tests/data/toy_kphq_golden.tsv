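node	role	k_phq
C1	candidate	3
C2	candidate	2
S1	seed	2
S2	seed	2
S3	seed	2
C3	candidate	1
C6	candidate	1
C4	candidate	0
C5	candidate	0
C7	candidate	0
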