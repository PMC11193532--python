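# Default GC-MS glucose fragment-ion configuration.
#
# Six fragment ions from three glucose derivatives (aldonitrile pentapropionate,
# methyloxime pentapropionate, di-O-isopropylidene acetate).  covered_atoms lists
# the glucose skeleton atoms the ion retains (C1..C6; H1..H7, with H6/H7 the two
# C6 hydrogens); formula is the full elemental composition of the ion including
# derivative atoms, used for natural-abundance correction.  Each formula's
# nominal mass equals the ion's lowest m/z, and the m/z window provides at least
# one channel per covered atom plus M+0.
# name	derivative	mz_lo	mz_hi	covered_atoms	formula
aldonitrile_173	aldonitrile	173	178	C5,C6,H5,H6,H7	C8H13O4
aldonitrile_259	aldonitrile	259	266	C4,C5,C6,H4,H5,H6,H7	C12H19O6
aldonitrile_284	aldonitrile	284	291	C1,C2,C3,H1,H2,H3	C13H18NO6
aldonitrile_370	aldonitrile	370	379	C1,C2,C3,C4,C5,H1,H2,H3,H4	C17H24NO8
methyloxime_145	methyloxime	145	149	C1,C2,H1,H2	C6H11NO3
diisopropylidene_301	di-O-isopropylidene	301	314	C1,C2,C3,C4,C5,C6,H1,H2,H3,H4,H5,H6,H7	C14H21O7
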