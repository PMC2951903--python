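# Screen concordance control: proteomically characterised T. brucei NPC set vs this screen
protein_id	orthology_established	outcome	fg_repeat_note	component
Tb10.61.2630	1	identified	0	Sec13
Tb11.01.5410	0	identified	0	Seh1
Tb11.02.2120	1	identified	0	Aladin
Tb09.160.2360	1	identified	0	Rae1
Tb10.6k15.2350	1	identified	0	Nup155
Tb11.02.0460	1	identified	0	Nup107
Tb10.6k15.3670	1	identified	0	Nup93
Tb1927.4.2880	1	identified	0	Nup205
Tb11.03.0140	1	identified	0	Nup96-98
Tb11.01.7200	1	identified	0	Nup62
Tb927.4.5200	1	identified	0	Nup54
Tb927.3.3180	0	excluded	1	
Tb927.3.3540	0	excluded	1	
Tb11.02.0270	0	excluded	1	
Tb11.01.2880	0	excluded	1	
Tb927.4.4310	0	excluded	1	
Tb927.8.8050	0	excluded	1	
Tb11.01.2885	0	excluded	1	
Tb11.03.0810	0	excluded	0	
Tb10.6k15.1530	0	not_detected	0	
Tb09.211.4780	0	not_detected	0	
Tb09.160.0340	0	not_detected	0	
Tb11.01.7630	0	not_detected	0	
Tb927.7.2300	0	not_detected	0	
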