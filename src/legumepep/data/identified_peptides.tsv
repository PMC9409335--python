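sequence	fraction	observed_mass_da	calculated_mass_da	precursor_protein	accession	start	end	modifications
NYDEGSEPR	F1	1066.421	1066.420	Convicilin	B0BCL8	29	37	1:deamidation
PVNRPGEPQ	F1	992.507	992.504	Vicilin	I0B569	152	160
LDNINALEPDH	F1	1250.578	1250.578	Legumin B	P05190.1	35	45	5:deamidation
TETWNPNHPE	F1	1223.522	1223.521	Legumin B	P05190.1	52	61
TETWNPNHPEL	F1	1336.606	1336.605	Legumin B	P05190.1	52	62
EEEDEDEPR	F1	1146.436	1146.431	Legumin	Q43673	327	335
KEEEDEDEPR	F1	1274.530	1274.526	Legumin	Q43673	326	335
VIPTEPPH	F1	888.470	888.471	Tonoplast intrinsic protein 32	A0A024NRI7	155	162
VIPTEPPHA	F1	959.508	959.508	Tonoplast intrinsic protein 32	A0A024NRI7	155	163
VVIPTEPPHA	F1	1058.577	1058.576	Tonoplast intrinsic protein 32	A0A024NRI7	154	163
VVIPTEPPH	F1 and F2	987.540	987.539	Tonoplast intrinsic protein 32	A0A024NRI7	154	162
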