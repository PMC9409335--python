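peptide	activity	fragments	a_printed
NYDEGSEPR	ACE inhibitor	PR,GS,EG,NY	0.44
NYDEGSEPR	stimulating	SE	0.11
NYDEGSEPR	DPP-IV inhibitor	EP,EG,NY,YD	0.44
NYDEGSEPR	DPP-III inhibitor	PR	0.11
PVNRPGEPQ	anti-amnestic	PG	0.11
PVNRPGEPQ	ACE inhibitor	GEP,RP,GE,PG,PQ	0.56
PVNRPGEPQ	antithrombotic	PG	0.11
PVNRPGEPQ	regulating	PG	0.11
PVNRPGEPQ	DPP-IV inhibitor	RP,EP,GE,NR,PG,PQ,PV,VN	0.89
PVNRPGEPQ	DPP-III inhibitor	GE	0.11
PVNRPGEPQ	renin inhibitor	NR	0.11
LDNINALEPDH	ACE inhibitor	ALEP	0.09
LDNINALEPDH	DPP-IV inhibitor	EP,AL,DN,IN,NA	0.45
TETWNPNHPE	ACE inhibitor	TE,HP	0.2
TETWNPNHPE	antioxidant	TW	0.1
TETWNPNHPE	alpha-glucosidase inhibitor	PE	0.1
TETWNPNHPE	DPP-IV inhibitor	HP,NP,WN,ET,NH,PN,TE,TW	0.8
TETWNPNHPE	DPP-III inhibitor	HP,PE	0.2
TETWNPNHPEL	ACE inhibitor	TE,HP	0.18
TETWNPNHPEL	antioxidant	EL,PEL,TW,TETWNPNHPEL	0.36
TETWNPNHPEL	alpha-glucosidase inhibitor	PE	0.09
TETWNPNHPEL	DPP-IV inhibitor	HP,NP,WN,ET,NH,PN,TE,TW	0.73
TETWNPNHPEL	DPP-III inhibitor	HP,PE	0.18
EEEDEDEPR	ACE inhibitor	PR	0.11
EEEDEDEPR	stimulating	EEE,EE	0.33
EEEDEDEPR	DPP-IV inhibitor	EP	0.11
EEEDEDEPR	DPP-III inhibitor	PR	0.11
KEEEDEDEPR	ACE inhibitor	PR,KE	0.2
KEEEDEDEPR	stimulating	EEE,EE	0.3
KEEEDEDEPR	DPP-IV inhibitor	EP,KE	0.2
KEEEDEDEPR	DPP-III inhibitor	PR	0.1
VIPTEPPH	ACE inhibitor	IP,TE,PT,PP,PH	0.63
VIPTEPPH	alpha-glucosidase inhibitor	PP	0.13
VIPTEPPH	DPP-IV inhibitor	PP,IP,EP,PH,PT,TE,VI	0.88
VIPTEPPHA	ACE inhibitor	IP,TE,PT,PP,PH	0.56
VIPTEPPHA	antioxidant	PHA	0.11
VIPTEPPHA	alpha-glucosidase inhibitor	PP	0.11
VIPTEPPHA	DPP-IV inhibitor	PP,HA,IP,EP,PH,PT,TE,VI	0.89
VVIPTEPPHA	ACE inhibitor	IP,TE,PT,PP,PH	0.5
VVIPTEPPHA	antioxidant	PHA	0.1
VVIPTEPPHA	alpha-glucosidase inhibitor	PP	0.1
VVIPTEPPHA	DPP-IV inhibitor	PP,VV,HA,IP,EP,PH,PT,TE,VI	0.9
VVIPTEPPH	ACE inhibitor	IP,TE,PT,PP,PH	0.56
VVIPTEPPH	alpha-glucosidase inhibitor	PP	0.11
VVIPTEPPH	DPP-IV inhibitor	PP,VV,IP,EP,PH,PT,TE,VI	0.89
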