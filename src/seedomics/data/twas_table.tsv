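trait	gene	lead_gwas_snp	gwas_p	twas_z	twas_p	annotation
Oil	Glyma.01G006900	Gm01:662815	1.48e-04	3.08	2.07e-03	Unknown function
Oil	Glyma.04G013800	Gm04:1012135	3.43e-04	3.58	3.43e-04	Jasmonate-zim-domain protein 1
Oil	Glyma.11G119100	Gm11:9122858	2.15e-10	3.19	1.41e-03	Unknown seed protein like 1
Oil	Glyma.12G064800	Gm12:4765210	1.08e-08	-3.83	1.28e-04	K-stimulated pyrophosphate-energized sodium pump protein
Oil	Glyma.12G103300	Gm12:8930945	2.29e-07	-4.06	4.87e-05	S-adenosyl-L-methionine-dependent methyltransferase
Oil	Glyma.12G135100	Gm12:15761610	2.49e-06	3.79	1.52e-04	Translation initiation factor SUI1 family protein
Oil	Glyma.12G141400	Gm12:17587181	1.27e-05	-3.52	4.36e-04	Cytokine-induced anti-apoptosis inhibitor 1, Fe-S biogenesis
Oil	Glyma.13G119900	Gm13:22203025	4.35e-05	3.23	1.25e-03	Novel plant snare 13
Oil	Glyma.13G130600	Gm13:23114123	3.55e-07	3.38	7.21e-04	Unknown function
Oil	Glyma.15G046700	Gm15:3658418	8.72e-08	4.35	1.34e-05	Maternal effect embryo arrest 9
Oil	Glyma.15G049800	Gm15:3658418	8.72e-08	-3.29	1.01e-03	Nodulin MtN21/EamA-like transporter family protein
Oil	Glyma.15G087400	Gm15:6771913	8.16e-06	-3.37	7.52e-04	Putative adipose-regulatory protein
Oil	Glyma.15G142600	Gm15:11253117	1.57e-05	3.24	1.18e-03	WD40/YVTN repeat-like-containing domain
Oil	Glyma.18G105900	Gm18:11849686	4.31e-05	3.57	3.61e-04	Galacturonosyltransferase 15
SW	Glyma.02G203800	Gm02:40313191	9.32e-05	3.16	1.57e-03	WRKY DNA-binding protein 32
SW	Glyma.06G323200	Gm06:50559402	8.46e-05	-3.02	2.54e-03	Unknown function
SW	Glyma.10G124300	Gm10:32983684	1.78e-07	-3.67	2.39e-04	Ankyrin repeat family protein
SW	Glyma.11G056000	Gm11:4099254	6.17e-05	3.55	3.92e-04	K-stimulated pyrophosphate-energized sodium pump protein
SW	Glyma.11G065900	Gm11:5054063	8.49e-06	3.69	2.20e-04	Protein phosphatase 2C family protein
SW	Glyma.12G064800	Gm12:4785599	9.58e-07	-3.36	7.92e-04	K-stimulated pyrophosphate-energized sodium pump protein
SW	Glyma.18G107000	Gm18:12273811	5.07e-06	-3.26	1.10e-03	Phosphoribosyltransferase family protein
SW	Glyma.19G147100	Gm19:40884584	3.69e-06	3.53	4.18e-04	KH domain-containing protein/zinc finger family protein
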