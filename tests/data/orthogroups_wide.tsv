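Orthogroup	spA	spB
OG0001	g1, g2	h1
OG0002	g3	h2, h3
OG0003		h4
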