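gene_id	s1	s2	s3	s4	s5	s6
g01	5	6	7	8	9	10
g02	2.0	2.0	0	0	0	0
g03	5	1.9	1.9	0	0	0
g04	0	0	0	0	0	0
g05	1.99	1.99	1.99	1.99	1.99	1.99
g06	2	1	2	1	2	1
g07	100	0	0	0	0	0
g08	3	3	3	3	3	3
g09	10	9	8	7	6	5
g10	0	2	0	2	0	0
g11	1	1	1	1	1	2
g12	2.5	0	0	0	0	2.5
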