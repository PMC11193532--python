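# Two-pool cycle with a scrambling return step (symmetric intermediate).
#METABOLITES
A	2	0	source
M	2	0	balanced
N	2	0	balanced
Out	2	0	sink
#REACTIONS
rin	0	A(C:ab) -> M(C:ab)
rfwd	0	M(C:ab) -> N(C:ab)
rback	0	N(C:ab) -> M(C:ab) || N(C:ab) -> M(C:ba)
rout	0	N(C:ab) -> Out(C:ab)
#TRACERS
A	input_a
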