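# Coatomer (COPI, COPII, clathrin/adaptin) component presence/absence across 46 eukaryote genomes
component	annotation	Am	Dm	Hs	Mm	Rn	Gg	Bt	Xl	Dr	Ci	Ce	Mb	Sc	Ps	Cg	Ca	Dh	Yl	Nc	An	Sp	Um	Cn	Ec	Eh	Dd	Cm	Vc	Ot	Cr	Pp	Os	At	Tt	Ptr	Pi	Tps	Tp	Ch	Tg	Pf	Pb	Gl	Ng	Tv	Li
alpha	COPI	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
beta	COPI	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
beta-prime	COPI		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
gamma	COPI	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x
delta	COPI	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
epsilon	COPI	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x		x	x	x	x	x	x	x	x	x	x	x	x	x			x				x	x	x
zeta	COPI	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
sar1	COPII	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
sec16	COPII	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x						x	x	x	x	x		x	x								x		
sec23	COPII	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
sec24	COPII	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
sec31	COPII	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
sfb3	COPII	x	x	x	x	x	x	x	x	x	x		x	x		x	x	x	x	x	x	x	x		x	x	x				x	x	x	x													
chc1	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
clc1	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x			x		x	x	x	x	x	x	x	x	x	x			x				x	x	x
apl1	Clathrin/AP			x	x	x	x	x	x	x				x	x	x	x	x	x	x	x	x		x																							
apl2	Clathrin/AP		x	x	x	x		x	x	x	x	x		x	x	x	x	x	x	x			x		x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
apl3	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x		x	x	x	x	x	x	x	x	x	x	x			x	x	x	x	x	x
apl4	Clathrin/AP		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x		x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x
apl5	Clathrin/AP	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x		x		x	x	x		x	x	x			x				x	x	x
apl6	Clathrin/AP	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x			x		x	x	x		x	x	x			x	x	x		x	x	x
apm1	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x
apm3	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x			x		x	x	x	x	x	x	x		x	x			x	x	x	x
apm4	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x		x	x	x	x	x	x	x	x	x	x			x	x	x	x	x	x	x
aps1	Clathrin/AP	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x		x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x		x	x	x
aps2	Clathrin/AP	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x		x	x		x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x
aps3	Clathrin/AP	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x		x	x	x		x	x	x			x	x	x		x	x	x
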