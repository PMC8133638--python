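node_a	node_b
S1	S2
S1	S3
S2	S3
S1	C1
S2	C1
S3	C1
S1	C2
S2	C2
S1	C3
C2	C3
C4	C5
S3	C6
C4	C7
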