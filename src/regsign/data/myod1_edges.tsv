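source	target	sign	directness	provenance
Mir96	Gpc1	-1	direct	synthetic reconstruction: microRNA represses its direct target
Gpc1	Myod1	+1	indirect	synthetic reconstruction: predicted upstream regulator favouring up
RegA	Myod1	+1	direct	synthetic reconstruction: known upstream regulator favouring down
Myod1	Igll1	+1	direct	synthetic reconstruction: known downstream gene favouring up
Myod1	Tgt1	+1	direct	synthetic reconstruction: known downstream gene favouring down
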