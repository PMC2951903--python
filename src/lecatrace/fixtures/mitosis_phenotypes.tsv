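# Mitosis mode per fungal genome (ascomycetes closed; basidiomycetes and zygomycete open)
genome	phenotype
An	closed
Yl	closed
Ps	closed
Nc	closed
Sp	closed
Sc	closed
Kl	closed
Ca	closed
Cg	closed
Dh	closed
Gz	closed
Mg	closed
Cn	open
Pc	open
Um	open
Lb	open
Cc	open
Ml	open
Ro	open
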