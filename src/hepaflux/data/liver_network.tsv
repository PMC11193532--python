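# Hepatic glucose-production / TCA-cycle atom-transition network (lumped).
#
# Carbon and tracked-hydrogen transitions for the dual 2H/13C tracer protocol
# ([6,6-2H2]glucose + 2H2O + [U-13C]propionate).  Linear chains without branch
# points are lumped into the single named flux that the field reports for them:
# V_CS spans citrate synthase through the succinyl-CoA pool (OAA + AcCoA ->
# SucCoA + 2 CO2), and V_SDH spans succinyl-CoA through the symmetric
# succinate/fumarate intermediates to oxaloacetate, written as two
# equiprobable atom-map variants to encode the molecular symmetry.
#
# Tracked hydrogens: glucose H positions 1-7 (H6/H7 = the two C6 hydrogens,
# the [6,6-2H2] tracer positions), plus the hydrogens of the PEP/pyruvate/OAA
# node that carry them: the PEP methylene pair, the pyruvate methyl (three
# equivalent hydrogens; pyruvate kinase adds one from water, pyruvate
# carboxylase removes a random one, written as three equiprobable variants),
# and the OAA C3 methylene pair.  Glucose H2 is water-equilibrated at glucose
# release (phosphoglucose-isomerase / transaldolase exchange) and the triose
# C2 hydrogen is water-derived on both gluconeogenic routes (triose-phosphate
# isomerase exchange).  On the V_SDH route (succinyl-CoA -> ... -> OAA) the
# OAA methylene acquires exactly one hydrogen from water (fumarase hydration
# of fumarate) while the other is retained from the succinate backbone, which
# derives from the unlabeled acetyl-CoA methyl (via citrate synthase) or
# propionate (via V_PCC); two tracked backbone hydrogens on succinyl-CoA
# carry this.  '@' marks solvent-derived hydrogens.
# CO2 is a well-mixed pool: its 13C labeling is the production-weighted
# mixture of the hepatic decarboxylation fluxes (V_PCK and the two V_CS
# decarboxylations), and it is refixed by pyruvate carboxylase (V_PC) and
# propionyl-CoA carboxylase (V_PCC); excess CO2 vents freely (no mass
# balance row).  Labeled CO2 entering succinyl-CoA C4 via V_PCC reaches
# glucose through the symmetric dicarboxylates, which is a key 13C signal
# for cataplerosis and pyruvate cycling.
#METABOLITES
Glc	6	7	sink
G6P	6	6	balanced
T3P	3	4	balanced
PEP	3	2	balanced
Pyr	3	3	balanced
OAA	4	2	balanced
SucCoA	4	2	balanced
GlcInf	6	7	source
Glycogen	6	6	source
Glycerol	3	3	source
Lac	3	3	source
AcCoA	2	2	source
Prop	3	2	source
CO2	1	0	pool
Water	0	1	source
#REACTIONS
V_inf	0	GlcInf(C:abcdef|H:ghijklm) -> Glc(C:abcdef|H:ghijklm)
V_EndoRa	0	G6P(C:abcdef|H:ghijkl) -> Glc(C:abcdef|H:g@hijkl)
V_PYGL	0	Glycogen(C:abcdef|H:ghijkl) -> G6P(C:abcdef|H:ghijkl)
V_Aldo	0	T3P(C:abc|H:defg) + T3P(C:hij|H:klmn) -> G6P(C:cbahij|H:fdklmn)
V_GK	0	Glycerol(C:abc|H:def) -> T3P(C:abc|H:d@ef)
V_Enol	0	PEP(C:abc|H:de) -> T3P(C:abc|H:@@de)
V_PCK	0	OAA(C:abcd|H:ef) -> PEP(C:abc|H:ef) + CO2(C:d)
V_PC	0	Pyr(C:abc|H:def) + CO2(C:g) -> OAA(C:abcg|H:de) || Pyr(C:abc|H:def) + CO2(C:g) -> OAA(C:abcg|H:df) || Pyr(C:abc|H:def) + CO2(C:g) -> OAA(C:abcg|H:ef)
V_LDH	0	Lac(C:abc|H:def) -> Pyr(C:abc|H:def)
V_PK+ME	0	PEP(C:abc|H:de) -> Pyr(C:abc|H:de@)
V_CS	0	OAA(C:abcd|H:ef) + AcCoA(C:gh|H:ij) -> SucCoA(C:cbhg|H:ij) + CO2(C:a) + CO2(C:d)
V_SDH	0	SucCoA(C:abcd|H:ef) -> OAA(C:abcd|H:@e) || SucCoA(C:abcd|H:ef) -> OAA(C:dcba|H:@f)
V_PCC	0	Prop(C:abc|H:ef) + CO2(C:d) -> SucCoA(C:abcd|H:ef)
#TRACERS
Water	body_water
GlcInf	glc_6_6_d2
Prop	u13c_propionate
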