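gene	protein_position	ref_aa	alt_aa	ref_class	alt_class
accD	91	R	C	basic	special
atpA	139	S	A	hydrophilic	hydrophilic
chlL	282	Q	K	acid/amide	basic
petL	44	K	Q	basic	acid/amide
rps15	63	V	I	hydrophobic	hydrophobic
ycf1	1525	I	L	hydrophobic	hydrophobic
ycf1	1559	L	I	hydrophobic	hydrophobic
ycf2	459	P	S	hydrophilic	hydrophilic
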