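sequence	activity	ec50_uM	reference
PR	ACE inhibitor		identified-peptide screen
GS	ACE inhibitor		identified-peptide screen
EG	ACE inhibitor		identified-peptide screen
NY	ACE inhibitor		identified-peptide screen
SE	stimulating		identified-peptide screen
EP	DPP-IV inhibitor		identified-peptide screen
EG	DPP-IV inhibitor		identified-peptide screen
NY	DPP-IV inhibitor		identified-peptide screen
YD	DPP-IV inhibitor		identified-peptide screen
PR	DPP-III inhibitor		identified-peptide screen
PG	anti-amnestic		identified-peptide screen
GEP	ACE inhibitor		identified-peptide screen
RP	ACE inhibitor		identified-peptide screen
GE	ACE inhibitor		identified-peptide screen
PG	ACE inhibitor		identified-peptide screen
PQ	ACE inhibitor		identified-peptide screen
PG	antithrombotic		identified-peptide screen
PG	regulating		identified-peptide screen
RP	DPP-IV inhibitor		identified-peptide screen
GE	DPP-IV inhibitor		identified-peptide screen
NR	DPP-IV inhibitor		identified-peptide screen
PG	DPP-IV inhibitor		identified-peptide screen
PQ	DPP-IV inhibitor		identified-peptide screen
PV	DPP-IV inhibitor		identified-peptide screen
VN	DPP-IV inhibitor		identified-peptide screen
GE	DPP-III inhibitor		identified-peptide screen
NR	renin inhibitor		identified-peptide screen
ALEP	ACE inhibitor		identified-peptide screen
AL	DPP-IV inhibitor		identified-peptide screen
DN	DPP-IV inhibitor		identified-peptide screen
IN	DPP-IV inhibitor		identified-peptide screen
NA	DPP-IV inhibitor		identified-peptide screen
TE	ACE inhibitor		identified-peptide screen
HP	ACE inhibitor		identified-peptide screen
TW	antioxidant		identified-peptide screen
PE	alpha-glucosidase inhibitor		identified-peptide screen
HP	DPP-IV inhibitor		identified-peptide screen
NP	DPP-IV inhibitor		identified-peptide screen
WN	DPP-IV inhibitor		identified-peptide screen
ET	DPP-IV inhibitor		identified-peptide screen
NH	DPP-IV inhibitor		identified-peptide screen
PN	DPP-IV inhibitor		identified-peptide screen
TE	DPP-IV inhibitor		identified-peptide screen
TW	DPP-IV inhibitor		identified-peptide screen
HP	DPP-III inhibitor		identified-peptide screen
PE	DPP-III inhibitor		identified-peptide screen
EL	antioxidant		identified-peptide screen
PEL	antioxidant		identified-peptide screen
TETWNPNHPEL	antioxidant		identified-peptide screen
EEE	stimulating		identified-peptide screen
EE	stimulating		identified-peptide screen
KE	ACE inhibitor		identified-peptide screen
KE	DPP-IV inhibitor		identified-peptide screen
IP	ACE inhibitor		identified-peptide screen
PT	ACE inhibitor		identified-peptide screen
PP	ACE inhibitor		identified-peptide screen
PH	ACE inhibitor		identified-peptide screen
PP	alpha-glucosidase inhibitor		identified-peptide screen
PP	DPP-IV inhibitor		identified-peptide screen
IP	DPP-IV inhibitor		identified-peptide screen
PH	DPP-IV inhibitor		identified-peptide screen
PT	DPP-IV inhibitor		identified-peptide screen
VI	DPP-IV inhibitor		identified-peptide screen
PHA	antioxidant		identified-peptide screen
HA	DPP-IV inhibitor		identified-peptide screen
VV	DPP-IV inhibitor		identified-peptide screen
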