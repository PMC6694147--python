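id	equation	lb	ub	gpr
EX_AX	AX ->	-10	1000	
EX_AY	AY ->	-10	1000	
FASTX	AX -> X	0	1000	gxf
SLOWX	AX -> X	0	1	
FASTY	AY -> Y	0	1000	gyf
SLOWY	AY -> Y	0	1	
BIOMASS	X + Y ->	0	1000	
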