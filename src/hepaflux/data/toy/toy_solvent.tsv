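# Solvent-hydrogen toy: B acquires two hydrogens from body water.
#METABOLITES
A	2	0	source
B	2	2	balanced
C	2	2	sink
Water	0	1	source
#REACTIONS
rhyd	0	A(C:ab) -> B(C:ab|H:@@)
rout	0	B(C:ab|H:cd) -> C(C:ab|H:cd)
#TRACERS
A	input_a
Water	body_water
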