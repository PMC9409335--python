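species	protein_family	protein	gene	accession
faba bean	Legumin (11S)	Legumin B	LEB4	P05190
faba bean	Legumin (11S)	Legumin B	LEB2	P16078
faba bean	Legumin (11S)	Legumin B	LEB6	P16079
faba bean	Legumin (11S)	Legumin B	LEB7	P16080
faba bean	Legumin (11S)	Legumin A	A1	Q03971
faba bean	Legumin (11S)	Legumin A	A2	Q99304
faba bean	Vicilin (7S)	Vicilin		P08438
faba bean	Vicilin (7S)	Convicilin		B0BCL8
faba bean	Vicilin (7S)	Convicilin		B0BCL7
pea	Legumin (11S)	Legumin B	LEGJ	P05692
pea	Legumin (11S)	Legumin B	LEGK	P05693
pea	Legumin (11S)	Legumin B	LEGB	P14594
pea	Legumin (11S)	Legumin A	A	P02857
pea	Legumin (11S)	Legumin A	A2	P15838
pea	Vicilin (7S)	Vicilin		P13918
pea	Vicilin (7S)	Convicilin	CVA	P13915
pea	Vicilin (7S)	Convicilin	CVB	P13919
soy	Glycinin (11S)	Glycinin-G1	GY1	P04776
soy	Glycinin (11S)	Glycinin-G2	GY2	P04405
soy	Glycinin (11S)	Glycinin-G3	GY3	P11828
soy	Glycinin (11S)	Glycinin-G4	GY4	P02858
soy	Glycinin (11S)	Glycinin-G5	GY5	P04347
soy	beta-Conglycinin (7S)	beta-Conglycinin-alpha'	CG-1	P11827
soy	beta-Conglycinin (7S)	beta-Conglycinin-alpha	CG-3	P0DO16
soy	beta-Conglycinin (7S)	beta-Conglycinin-beta	CG-4	P25974
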