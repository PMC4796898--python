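gene	state	tier
Mir96	down	qrt_confirmed
Igll1	up	array_reported
Tgt1	down	array_reported
RegA	down	qrt_confirmed
Gpc1	up	predicted
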