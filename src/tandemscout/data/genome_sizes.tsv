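# Genome sizes (pg/1C) for the Andropogoneae panel and outgroups
Apluda mutica	1.79
Arundinella nepalensis	2.02
Hyparrhenia hirta	1.86
Ischaemum rugosum	0.75
Oryza sativa	0.50
Phyllostachys edulis	2.1
Sorghum bicolor	0.75
Tripsacum andersonii	5.8
Tripsacum dactyloides	3.88
Tripsacum floridanum	3.47
Tripsacum laxum	3.04
Tripsacum peruvianum	4.55
Triticum urartu	4.93
Urelytrum digitatum	0.73
Zea mays	2.73
Zea perennis	5.28
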