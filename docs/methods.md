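# Methods

`hepaflux` estimates hepatic glucose-production and TCA-cycle fluxes from the
mass isotopomer distributions (MIDs) of plasma-glucose fragment ions measured
by GC-MS during a three-tracer infusion: a ²H₂O bolus enriching total body
water to 4.5%, a primed continuous [6,6-²H₂]glucose infusion
(4.4 µmol/kg/min, 440 µmol/kg prime), and a primed continuous
[U-¹³C]propionate infusion (55 µmol/kg/min, 1.1 mmol/kg prime). This note
records the model, its assumptions, the numerical choices, and what the
synthetic-data tests do and do not establish.

## The atom-transition network

The default network (`data/liver_network.tsv`) couples ordinary stoichiometry
with per-atom carbon and hydrogen transition maps. It exposes exactly the
thirteen fluxes the analysis reports: the glucose-producing pathway
(`V_EndoRa`, `V_PYGL`, `V_Aldo`, `V_Enol`, `V_GK`), the TCA/anaplerotic
fluxes (`V_CS`, `V_SDH`, `V_PC`, `V_PCK`, `V_PCC`, `V_LDH`, `V_PK+ME`), and
the tracer-glucose infusion `V_inf`. Linear chains without branch points are
lumped into the single flux the field reports for them: `V_CS` spans citrate
synthase through the succinyl-CoA pool (OAA + AcCoA → SucCoA + 2 CO₂, the
two decarboxylations releasing the OAA-derived carboxyls), and `V_SDH` spans
succinyl-CoA through succinate/fumarate/malate to oxaloacetate. Passage
through the symmetric dicarboxylic acids is encoded as two equiprobable
atom-map variants (`abcd` / `dcba`); the pyruvate-carboxylase hydrogen
abstraction from the rotationally equivalent methyl is encoded as three
equiprobable variants. Lumping pyruvate kinase with malic enzyme
(`V_PK+ME`: PEP → pyruvate) is exact for carbon because PEPCK drops the same
OAA carboxyl that malic enzyme would.

CO₂ is a well-mixed *pool*: isotopically balanced (its ¹³C content is the
production-weighted mixture of the V_PCK and V_CS decarboxylations) but
stoichiometrically vented, i.e. it carries no mass-balance row and its
excess leaves freely. Refixation by pyruvate carboxylase and propionyl-CoA
carboxylase returns labeled CO₂ to the network; the PCC route (CO₂ →
succinyl-CoA C4 → scrambled dicarboxylates → OAA C1 → PEP → glucose) is a
key ¹³C signal for cataplerosis. Treating hepatic CO₂ as fed only by the
network's own decarboxylations overstates its enrichment relative to a
whole-body bicarbonate pool; this is a deliberate single-compartment
simplification.

### Hydrogen model

Only hydrogens with informative transitions are tracked; `@` in the network
file marks positions acquired from body water:

* glucose H2 is fully water-exchanged at glucose release
  (phosphoglucose-isomerase/transaldolase equilibration), so it reports
  total glucose turnover;
* the triose C2 hydrogen (glucose H5) is water-derived on both gluconeogenic
  routes (TPI equilibration), reporting total gluconeogenesis;
* the PEP methylene hydrogens (glucose H6/H6') and the C1 hydride of the
  triose (glucose H4) are water-derived on the PEP route only, separating
  phosphoenolpyruvate-derived from glycerol-derived gluconeogenesis;
* the pyruvate methyl is tracked explicitly: pyruvate kinase adds one water
  hydrogen, pyruvate carboxylase removes a random one of the three
  equivalents, so every pyruvate-cycling pass mixes body water into the
  hydrogens that reach glucose C6 — the signal that makes `V_PK+ME` (and
  through the balances `V_PCK`, `V_PC`) identifiable at all;
* on the `V_SDH` route the OAA methylene acquires exactly one hydrogen from
  water (fumarase hydration of fumarate); the other is retained from the
  succinate backbone, which derives from the unlabeled acetyl-CoA methyl or
  propionate. Modeling *both* as water-derived (full equilibration) places
  the true labeling state within one noise SD of the large-cycling
  saturation limit and makes the cycling flux practically unidentifiable;
  the one-water-hydrogen chemistry is both sharper and more faithful.

Hydrogens may be released to the solvent (e.g. PEP → pyruvate drops the
methylene pair); carbon maps are strictly conserving. The file format
requires every product atom to have exactly one source (a reactant atom or
`@`).

## EMU simulation

Steady-state MIDs are computed with the elementary-metabolite-unit
decomposition: the atoms needed for the six measured fragments are traced
backward through the atom maps, and per EMU size the linear balance system
`A(v)·X = B(v)·Y` is solved densely, with condensations entering as Cauchy
products (convolutions) of smaller EMUs. Both heavy isotopes shift nominal
mass by +1 Da, so ²H and ¹³C share one pooled mass dimension, as a
quadrupole GC-MS resolves. The default decomposition has ~124 EMUs (the full
isotopomer description would need 2¹³ states for glucose alone) and one
simulation takes under a millisecond, which is what makes the
multistart regression and the replicate studies below affordable.

Rows are scaled by total production before solving; an EMU whose pool
receives no production flux raises an identifiability error naming it.
Returned MIDs are clipped at 0 and renormalized (drift ≤ 1e-12).

The independent correctness oracle is a full isotopomer-enumeration
simulator (`hepaflux.isotopomer`): every metabolite's joint 2ⁿ labeling
distribution is balanced by fixed-point iteration, with each update
renormalized to unit mass (in exact arithmetic mass is conserved; in
floating point, condensations inside cycles amplify sub-ulp mass deficits
multiplicatively, so the unit-sum manifold must be enforced). The EMU
cascade matches this oracle to ~1e-13 on four toy networks (chain,
condensation, scrambling cycle, solvent-hydrogen acquisition) over random
balanced flux vectors, and on the full liver network.

Tracer inputs are two-component mixtures: a fraction `enrichment` of tracer
molecules whose designated positions are heavy with probability `purity`
(other positions at natural abundance), plus the natural-abundance
complement. For the default tracers (enrichment 1, or the single-atom water
pool) this coincides with per-atom independence.

## Measurement model

Each of the six fragment ions (aldonitrile pentapropionate m/z 173–178,
259–266, 284–291, 370–379; methyloxime m/z 145–149; di-O-isopropylidene
m/z 301–314) covers a subset of the glucose skeleton atoms and adds
derivative atoms whose natural isotope abundance spreads the signal over the
m/z window. The packaged fragment table assigns atom coverage from the
derivatization chemistry (complementary windows from both ends of the
molecule plus the whole skeleton in the di-O-isopropylidene ion) and ion
formulas whose nominal mass equals the window's low m/z; each window
provides at least one channel per covered atom. These assignments are
package configuration, editable in `data/fragments.tsv`.

The forward map convolves a skeleton MID with the natural MID of the
derivative atoms, truncates to the window and renormalizes; fitting happens
in this observable space. The inverse (least-squares solve of the
quasi-triangular system) is provided for diagnostics and flags entries below
−0.01 as irreconcilable data. Skeleton-atom natural abundance (¹³C 0.0107,
²H 0.000115) is applied inside the tracer inputs; derivative-atom abundance
lives here — biology and chemistry corrections stay separate. Unenriched
pre-infusion samples are validated channel-wise against the theoretical
natural MID of the full ion (default threshold 0.005 mole fraction).

## Regression, goodness of fit, intervals

With citrate synthase constrained to an arbitrary 100, the flux space is
parameterized by six free fluxes (`V_inf`, `V_PYGL`, `V_GK`, `V_Enol`,
`V_PK+ME`, `V_PCC`) obtained from the constrained null space; the remaining
fluxes are affine in these. Bounded trust-region least squares (SciPy
`least_squares`, finite-difference Jacobian, ftol/xtol/gtol 1e-12) minimizes
the variance-weighted SSR over the 51 measured channels; restarts (default
50) draw starts log-uniformly over [10⁻², 10²] × the normalization scale,
and the best SSR wins. Dependent fluxes are kept nonnegative by a smooth
penalty that is inactive at every feasible point. Exchange fluxes of
reversible reactions (none in the default network) are optimized through the
bounded transform u/(1−u)·100. A fixed seed makes the whole procedure
bit-reproducible.

Goodness of fit uses the two-sided 95% χ² band with dof = channels −
free parameters (51 − 6 = 45). Confidence intervals are profile likelihood:
the named flux (free or dependent) is fixed at a trial value, all other
free fluxes re-optimized, and the 95% bound is where the profiled SSR
crosses SSR_min + 3.84; the lower bound is truncated at 0 and an uncrossed
upper bound is reported as +∞. Relative fluxes scale to absolute
µmol/kg/min through the known infusion: scale = 4.4 / relative(V_inf), which
makes the absolute result independent of the arbitrary normalization value.

### Error model and its calibration

The synthetic-data generator adds independent Gaussian error
(SD 0.003 mole fraction, the duplicate-injection scale) to each channel of
the true observable MIDs and records that SD exactly; duplicate injections
are averaged at load with SD/√2. The noisy fractions are deliberately *not*
renormalized to unit sum: any renormalization (at generation or at load)
correlates the channels, and the diagonally weighted SSR then becomes a
generalized χ² with Σλ² ≈ 62 instead of 51 — empirically ~0.88 acceptance
against the nominal χ²(45) band instead of 0.95. With independent errors the
calibration is clean: across 500 replicate fits at the true fluxes the SSR
has mean ≈ 45 and the two-sided 95% band accepts ≈ 95%, and profile-CI
coverage for endogenous glucose production is ≈ 93–96% over 200 replicates.
When no SD column is available (real data), the per-channel SD defaults to
max(0.003, duplicate half-range).

## Identifiability at the study design

Fisher-information analysis at the rest condition (single animal, duplicate
injections, SD 0.003) gives approximate relative SDs: EndoRa ≈ 4%,
V_PYGL ≈ 7%, V_Enol ≈ 6%, V_LDH ≈ 9%, V_SDH ≈ 1%, V_PCC ≈ 4%, V_GK ≈ 38%,
and V_PK+ME ≈ 115% — pyruvate cycling is intrinsically weakly identified,
and V_PCK = V_Enol + V_PK+ME and V_PC = V_PCK − V_PCC inherit its
uncertainty (~35–45%). The likelihood in the cycling direction saturates, so
a second basin with inflated cycling is occasionally (a few percent of
cohort-level replicates) the global optimum under noise; profile intervals
report this honestly as wide or unbounded upper limits. Group contrasts
(e.g. suppressed V_PC in the knockout scenarios) are therefore assessed on
cohort-averaged measurements (n = 8 animals), where they separate in ≳ 90%
of seeded replicates.

## Synthetic scenarios

Scenario flux magnitudes are illustrative, physiologically ordered
configuration for the fasted mouse — EndoRa ≈ 150 µmol/kg/min at rest with
roughly ¾ gluconeogenic, TCA flux V_CS ≈ 130 — and are not values extracted
from any experiment. Knockout ("DKO") scenarios suppress pyruvate-driven
anaplerosis (V_PC to < 0.2× rest) and unlabeled anaplerotic inflow;
exercise scenarios raise glycogenolysis, PEP-gluconeogenesis and TCA flux,
and use the matching rest truth for the pre-exercise 0-min sample. Each
animal differs only by measurement noise: the generator emulates
instrument/injection variability, not biological between-animal variance,
pharmacokinetics of the bolus (body water is held at 4.5%), instrument
drift, or chromatographic artifacts — so passing tests validate the
estimator under the stated error model, not robustness to real-data
pathologies.

Replicate studies (χ² calibration, CI coverage, cohort contrasts) start the
single regression per replicate at the generating truth plus, where noted,
random restarts; this is a computational shortcut to the global optimum that
the 50-restart default finds from scratch, chosen to keep the full
calibration (500 + 200 replicates) within minutes on one CPU.

## Known limitations

* Transitions are a lumped single-compartment liver model; no
  compartmentation, no exchange (reversible) fluxes in the default network,
  no isotopically nonstationary dynamics.
* The CO₂ pool ignores whole-body bicarbonate dilution (overstates
  refixation labeling).
* Fragment atom coverage and ion formulas are package configuration
  constrained by chemistry and nominal mass, not instrument-derived.
* V_PK+ME is weakly identified at the default noise; treat its point
  estimates (and to a lesser degree V_PCK, V_PC) through their profile
  intervals rather than at face value.
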