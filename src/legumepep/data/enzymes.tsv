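enzyme_id	ec_number	p1_residues	p1prime_blockers	description
pepsin	3.4.23.1	FL		pepsin (pH > 2), cleaves after F or L
trypsin	3.4.21.4	KR	P	cleaves after K or R, blocked by following P
chymotrypsin	3.4.21.1	FYW	P	alpha-chymotrypsin (high specificity), cleaves after F/Y/W, blocked by following P
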