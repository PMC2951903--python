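# Nucleoporin presence/absence across 51 eukaryote genomes (HMM screen, species-level detail)
component	annotation	Ag	Am	Dm	Hs	Mm	Rn	Gg	Xl	Dr	Tn	Ci	Ce	Mb	Sc	Kl	Ps	Cg	Ca	Dh	Yl	Nc	Gz	An	Mg	Sp	Um	Cn	Ec	Eh	Dd	Cm	Vc	Ot	Cr	Pp	Pt	Os	At	Tt	Ptr	Pi	Tps	Tp	Ch	Tg	Pb	Gl	Ng	Tv	Tb	Lm
Gle1	cytoplasmic fibrils	x	x	x	x	x	x	x		x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x	x		x	x	x	x	x	x		x	x	x		x				x			
Aladin	cytoplasmic fibrils	x		x	x	x	x	x	x	x	x	x		x																	x	x	x	x		x	x	x	x			x							x		x	x
Nup88	cytoplasmic fibrils	x	x	x	x	x	x	x	x	x	x	x			x	x	x	x	x	x	x	x	x	x	x	x	x	x			x	x	x	x	x	x	x	x	x			x										
Nup214	cytoplasmic fibrils	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x			x			x	x	x			x				x			x			x
Nup358	cytoplasmic fibrils	x	x	x	x	x	x	x	x	x	x	x	x	x																																						
Nup160	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x		x	x		x	x	x	x			x							x			
Nup133	scaffold	x	x	x	x	x	x	x		x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x			x	x	x	x	x	x	x	x	x		x	x	x						x			
Nup107	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x	x	x	x		x	x	x	x		x	x	x					x	x	x	x	x
Nup75	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x		x	x	x	x	x	x	x			x							x			
Nup43	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x																	x					x	x	x	x			x										
Nup37	scaffold	x	x	x	x	x	x	x	x	x	x	x									x	x	x	x	x	x																										
Seh1	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x		x		x			x	x	x	x	x	x	x	x	x	x	x	x							x		x	x
Sec13	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x
Nup205	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x					x	x	x	x	x	x	x			x							x	x	x	x
Nup188	scaffold	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x					x	x	x	x	x	x	x													
Nup155	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x		x			x	x	x	x	x
Nup93	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x		x	x	x	x	x	x	x	x	x						x	x	x	x
Nup35	scaffold	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x					x		x	x		x	x	x	x	x	x	x	x	x		x	x	x					x		x		
Ndc1	transmembrane	x		x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x						x	x	x	x	x	x			x								x		
Pom121	transmembrane				x	x	x	x	x	x	x																																									
Gp210	transmembrane	x	x	x	x	x	x	x	x	x	x	x	x	x																x	x					x	x	x	x	x				x	x	x			x	x		
Pom152	transmembrane														x	x	x	x	x	x	x	x	x	x	x	x	x	x																								
Pom34	transmembrane														x	x	x	x	x	x	x	x	x	x	x	x																										
Nup96-98	nuclear ring	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x
Rae1	nuclear ring	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x		x	x
Nup62	central channel	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x		x	x	x		x	x			x	x	x	x
Nup58	central channel	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x		x		x	x	x	x	x			x							x			x
Nup54	central channel	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x	x	x	x	x	x	x	x	x	x	x	x	x			x		x	x	x	x	x
Nup50	nuclear basket	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x			x			x			x	x	x		x	x	x						x			
Nup153	nuclear basket		x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x					x	x	x						x			x	x	x		x	x	x						x			
TPR	nuclear basket	x	x	x	x	x	x	x	x	x	x	x	x	x	x	x		x	x	x	x	x	x	x	x	x	x	x			x		x	x		x	x	x	x		x	x	x						x			
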