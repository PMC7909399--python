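function	match_rule
photoautotrophy	Cyanobacteria
photoautotrophy	Chlorobi
chemoheterotrophy	Flavobacterium
chemoheterotrophy	Pseudomonas
chemoheterotrophy	Limnohabitans
chemoheterotrophy	Rhodobacter
methanotrophy	Methylococcaceae
methylotrophy	Methylococcaceae
methylotrophy	Methylophilaceae
fermentation	Clostridium
fermentation	Lactobacillus
nitrogen_fixation	Cyanobacteria
nitrogen_fixation	Clostridium
denitrification	Pseudomonas
denitrification	Paracoccus
nitrification	Nitrosomonas
nitrification	Nitrospira
nitrogen_respiration	Nitrosomonas
nitrogen_respiration	Pseudomonas
aerobic_chemoheterotrophy	Flavobacterium
aerobic_chemoheterotrophy	Limnohabitans
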