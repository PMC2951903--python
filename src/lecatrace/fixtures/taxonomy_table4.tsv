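# Fungal genome panel for the anchoring-Nup screen
genome	species	class	supergroup
An	Aspergillus nidulans	Ascomycetes	Opisthokonts
Yl	Yarrowia lipolytica	Ascomycetes	Opisthokonts
Ps	Pichia stipitis	Ascomycetes	Opisthokonts
Nc	Neurospora crassa	Ascomycetes	Opisthokonts
Sp	Schizosaccharomyces pombe	Ascomycetes	Opisthokonts
Sc	Saccharomyces cerevisiae	Ascomycetes	Opisthokonts
Kl	Kluyveromyces lactis	Ascomycetes	Opisthokonts
Ca	Candida albicans	Ascomycetes	Opisthokonts
Cg	Candida glabrata	Ascomycetes	Opisthokonts
Dh	Debaryomyces hansenii	Ascomycetes	Opisthokonts
Gz	Gibberella zeae	Ascomycetes	Opisthokonts
Mg	Magnaporthe grisea	Ascomycetes	Opisthokonts
Cn	Cryptococcus neoformans	Basidiomycetes	Opisthokonts
Pc	Phanerochaete chrysosporium	Basidiomycetes	Opisthokonts
Um	Ustilago maydis	Basidiomycetes	Opisthokonts
Lb	Laccaria bicolor	Basidiomycetes	Opisthokonts
Cc	Coprinopsis cinerea	Basidiomycetes	Opisthokonts
Ml	Malassezia globosa	Basidiomycetes	Opisthokonts
Ro	Rhizopus oryzae	Zygomycetes	Opisthokonts
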