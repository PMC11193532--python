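# Condensation toy: X + Y -> Z with interleaved carbons, Z -> P sink.
#METABOLITES
X	2	0	source
Y	2	0	source
Z	4	0	balanced
P	4	0	sink
#REACTIONS
rc	0	X(C:ab) + Y(C:cd) -> Z(C:badc)
rout	0	Z(C:abcd) -> P(C:abcd)
#TRACERS
X	input_x
Y	input_y
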