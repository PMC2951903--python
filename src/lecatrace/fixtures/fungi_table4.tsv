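# Anchoring nucleoporins across 19 fungal genomes
component	An	Yl	Ps	Nc	Sp	Sc	Kl	Ca	Cg	Dh	Gz	Mg	Cn	Pc	Um	Lb	Cc	Ml	Ro
Ndc1	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
Pom152	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
Pom34	x	x	x	x	x	x	x	x	x	x	x	x							
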