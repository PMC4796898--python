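panel	gene	p_raw
confirmation	Chrna1	0.28
confirmation	Gtf2e2	0.84
confirmation	Rasd2	0.03
confirmation	Odf3b	0.03
confirmation	Dynlrb2	0.03
confirmation	Meig1	0.03
confirmation	Bhlhe40	0.02
confirmation	Homer1	0.28
confirmation	Morn5	0.02
confirmation	Myo3a	0.02
intermediates	Foxo3	0.28
intermediates	Mitf	0.63
intermediates	Htt	0.84
intermediates	Thrb	0.28
intermediates	Foxo1	1
intermediates	Nr3c1	0.95
intermediates	Zic2	0.03
intermediates	Tnc	0.28
intermediates	Pou4f3	0.03
ago2_candidates	Gnb4	0.28
ago2_candidates	Tmem97	0.84
ago2_candidates	Sox5	0.95
ago2_candidates	Zfp251	0.28
ago2_candidates	Ablim1	0.84
ago2_candidates	Clvs1	0.84
ago2_candidates	Mpv17l	0.84
ago2_candidates	Ankrd27	0.28
network_candidates	Fos	0.02
network_candidates	Ets1	0.84
network_candidates	Tgfb1	1
network_candidates	Sp1	0.63
network_candidates	Myc	1
network_candidates	Agt	0.63
network_candidates	Rhoa	1
network_candidates	Trp53	0.21
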