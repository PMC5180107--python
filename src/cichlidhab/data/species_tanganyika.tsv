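name	abbreviation	tribe	ecomorph	territoriality
Xenotilapia papilio	Xpap	Ectodini	scooper	partial
Eretmodus cyanostictus	Ecya	Eretmodini	scraper	partial
Telmatochromis temporalis	Ttem	Lamprologini	browser	territorial
Telmatochromis vittatus	Tvit	Lamprologini	browser	none
Variabilichromis moorii	Vmoo	Lamprologini	browser	territorial
Interochromis loocki	Iloo	Tropheini	grazer	partial
Limnotilapia dardennii	Ldar	Tropheini	browser	none
Pseudosimochromis curvifrons	Pcur	Tropheini	browser	partial
Petrochromis famula	Pfam	Tropheini	grazer	partial
Petrochromis fasciolatus	Pfas	Tropheini	grazer	none
Petrochromis polyodon	Ppol	Tropheini	grazer	territorial
Petrochromis horii	Phor	Tropheini	grazer	territorial
Petrochromis trewavasae	Ptre	Tropheini	grazer	territorial
Simochromis diagramma	Sdia	Tropheini	browser	none
Tropheus moorii	Tmoo	Tropheini	browser	territorial
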