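name	taxa	mean_Ma	sd_Ma
Caniformia/Feliformia		51.65	7.3
Rodentia/Lagomorpha		110.3	27.8
Rodentia/Primates		112.95	26.4
Euarchontoglires/Laurasiatheria		112.95	26.4
Xenarthra/Boreoeutheria		112.95	26.4
Afrotheria/Boreoeutheria		112.95	26.4
Australidelphia/Ameridelphia		89.45	21.4
Marsupialia/Placentalia		162.95	3.4
CrownMammalia		183.2	9.8
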