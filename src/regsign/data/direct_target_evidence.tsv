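gene	category	citation
Foxo1	literature_confirmed	reported target, other tissues
Foxo3	literature_confirmed	reported target, other tissues
Mitf	literature_confirmed	reported target, other tissues
Adcy6	literature_confirmed	reported target, other tissues
Clic5	literature_confirmed	reported target, other tissues
Scarb1	literature_confirmed	reported target, other tissues
Nr3c1	literature_confirmed	reported target, other tissues
Scn3a	literature_confirmed	reported target, other tissues
Spast	literature_confirmed	reported target, other tissues
Gpc3	literature_confirmed	reported target, other tissues
Insig2	literature_confirmed	reported target, other tissues
Irs1	literature_confirmed	reported target, other tissues
Slc1a1	literature_confirmed	reported target, other tissues
Gpc1	literature_confirmed	reported target, other tissues
Alk	literature_confirmed	reported target, other tissues
Rad51	literature_confirmed	reported target, other tissues
Rev1	literature_confirmed	reported target, other tissues
Hbp1	literature_confirmed	reported target, other tissues
Reck	literature_confirmed	reported target, other tissues
Aqp5	luciferase_confirmed	luciferase assay
Celsr2	luciferase_confirmed	luciferase assay
Odf2	luciferase_confirmed	luciferase assay
Hspa2	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
Pnpla8	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
Sdc2	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
Arf2	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
Casc1	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
Gad2	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
St8sia3	upregulated_with_seed_match	upregulated at P4 and P0, seed match in 3'UTR
Zic2	predicted_and_expressed	predicted target, upregulated at P4
Osbpl2	predicted_and_expressed	predicted target, expressed in outer hair cell stereocilia
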