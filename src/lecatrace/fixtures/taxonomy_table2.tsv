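# Genome code -> species, taxonomic class, eukaryote supergroup (nucleoporin screen panel)
genome	species	class	supergroup
Ag	Anopheles gambiae	Dipterans	Opisthokonts
Am	Apis mellifera	Dipterans	Opisthokonts
Dm	Drosophila melanogaster	Dipterans	Opisthokonts
Hs	Homo sapiens	Vertebrates	Opisthokonts
Mm	Mus musculus	Vertebrates	Opisthokonts
Rn	Rattus norvegicus	Vertebrates	Opisthokonts
Gg	Gallus gallus	Vertebrates	Opisthokonts
Xl	Xenopus laevis	Vertebrates	Opisthokonts
Dr	Danio rerio	Vertebrates	Opisthokonts
Tn	Tetraodon nigroviridis	Vertebrates	Opisthokonts
Ci	Ciona intestinalis	Tunicates	Opisthokonts
Ce	Caenorhabditis elegans	Nematodes	Opisthokonts
Mb	Monosiga brevicollis	Choanoflagellates	Opisthokonts
Sc	Saccharomyces cerevisiae	Ascomycetes	Opisthokonts
Kl	Kluyveromyces lactis	Ascomycetes	Opisthokonts
Ps	Pichia stipitis	Ascomycetes	Opisthokonts
Cg	Candida glabrata	Ascomycetes	Opisthokonts
Ca	Candida albicans	Ascomycetes	Opisthokonts
Dh	Debaryomyces hansenii	Ascomycetes	Opisthokonts
Yl	Yarrowia lipolytica	Ascomycetes	Opisthokonts
Nc	Neurospora crassa	Ascomycetes	Opisthokonts
Gz	Gibberella zeae	Ascomycetes	Opisthokonts
An	Aspergillus nidulans	Ascomycetes	Opisthokonts
Mg	Magnaporthe grisea	Ascomycetes	Opisthokonts
Sp	Schizosaccharomyces pombe	Ascomycetes	Opisthokonts
Um	Ustilago maydis	Basidiomycetes	Opisthokonts
Cn	Cryptococcus neoformans	Basidiomycetes	Opisthokonts
Ec	Encephalitozoon cuniculi	Microsporidia	Opisthokonts
Eh	Entamoeba histolytica	Amoebozoa	Amoebozoa
Dd	Dictyostelium discoideum	Amoebozoa	Amoebozoa
Cm	Cyanidioschyzon merolae	Rhodophytes	Plantae
Vc	Volvox carteri	Chlorophytes	Plantae
Ot	Ostreococcus lucimarinus	Chlorophytes	Plantae
Cr	Chlamydomonas reinhardtii	Chlorophytes	Plantae
Pp	Physcomitrella patens	Streptophytes	Plantae
Pt	Populus trichocarpa	Streptophytes	Plantae
Os	Oryza sativa	Streptophytes	Plantae
At	Arabidopsis thaliana	Streptophytes	Plantae
Tt	Tetrahymena thermophila	Ciliates	Chromalveolates
Ptr	Phaeodactylum tricornutum	Heterokonts	Chromalveolates
Pi	Phytophthora infestans	Heterokonts	Chromalveolates
Tps	Thalassiosira pseudonana	Heterokonts	Chromalveolates
Tp	Theileria parva	Apicomplexans	Chromalveolates
Ch	Cryptosporidium hominis	Apicomplexans	Chromalveolates
Tg	Toxoplasma gondii	Apicomplexans	Chromalveolates
Pb	Plasmodium berghei	Apicomplexans	Chromalveolates
Gl	Giardia lamblia	Diplomonads	Excavates
Ng	Naegleria gruberi	Heterolobosea	Excavates
Tv	Trichomonas vaginalis	Parabasalids	Excavates
Tb	Trypanosoma brucei	Kinetoplastids	Excavates
Lm	Leishmania major	Kinetoplastids	Excavates
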