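id	equation	lb	ub	gpr
EX_A	A ->	-10	1000	
ISO1	A -> B	0	1000	g1
ISO2	A -> B	0	1000	g2
ISO3	A -> B	0	1000	g3
BIOMASS	B ->	0	1000	
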