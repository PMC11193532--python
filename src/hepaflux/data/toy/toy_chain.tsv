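# Linear two-step chain: source A -> B -> sink C, identity carbon maps.
#METABOLITES
A	2	0	source
B	2	0	balanced
C	2	0	sink
#REACTIONS
r1	0	A(C:ab) -> B(C:ab)
r2	0	B(C:ab) -> C(C:ab)
#TRACERS
A	input_a
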