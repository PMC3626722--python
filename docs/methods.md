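# Methods

`instaflux` models an instationary 13C labelling experiment in a chemostat
culture of *Pichia pastoris* co-assimilating glucose and methanol, and the
companion analyses: flux and pool-size estimation from mass-isotopomer
dynamics, network-embedded thermodynamic (NET) validation of metabolite
concentrations, and macroscopic/cofactor balance accounting.

## The labelling model

Fluxes are at metabolic steady state while isotope labelling is transient:
after the feed switches to 80% [1-13C1] + 20% [U-13C6] glucose and 100%
13C methanol, each intracellular pool washes toward its isotopic steady
state at a rate set by its flux-to-pool ratio. The state variables are
mass-isotopomer distributions (MIDs) of elementary metabolite units
(EMUs): carbon subsets whose labelling balances close on themselves. For
an EMU hosted by a pool of size `c` (umol/gCDW),

    c * dx/dt = sum_j f_j * (x_src(j) - x),

with `f_j` the producing flux (mmol/gCDW/h; forward or backward flux of a
reversible step) and `x_src(j)` the source MID — a feed MID, another EMU's
MID, or a convolution of EMU MIDs for condensation reactions. Because the
flux field is stationary, outflow leaves at pool composition and no
separate growth-dilution term is needed; biomass drains are ordinary
efflux reactions. The EMU formulation is equivalent to cumulative-
isotopomer (cumomer) balancing but integrates far fewer variables; the
equivalence is enforced in the test suite by comparing against a
brute-force positional-isotopomer ODE system (all 2^n states) on small
networks, to 1e-6 in every fraction.

Numerical choices: stiff BDF integration with relative tolerance 1e-8 and
absolute tolerance 1e-10 by default, because flux-to-pool ratios span
roughly four orders of magnitude (sub-second turnover of oxaloacetate
versus hours for glutamate and trehalose); a block sparsity pattern of the
EMU coupling is passed to the solver. The stationary solver solves the
same balances algebraically, cascading by EMU size (convolution sources
only ever involve strictly smaller EMUs); a singular within-size system
means a flux-disconnected EMU and is reported as such. Simulated MIDs are
checked to remain normalised to 1e-6 and renormalised on output.

Symmetric metabolites (succinate, fumarate, dihydroxyacetone) scramble
their carbon orientation: the parser supports alternative right-hand
sides weighted equally within one reaction, and the packaged network
additionally ships the four symmetric-product fluxes (DAS, SDH, fumarase
forward/backward) as explicit a/b variant pairs tied 1:1 in the
constraint file, which reproduces the original constraint bookkeeping.
CO2 consumed by pyruvate carboxylase is treated as unlabelled, since CO2
enrichment is not measured; CO2 is balanced stoichiometrically (it closes
the carbon balance and makes the CO2 evolution rate a usable constraint)
but carries no labelling state.

## The packaged network

The reduced central-carbon network is reconstructed from the published
model description: glycolysis/gluconeogenesis including FBPase, oxidative
and non-oxidative PPP, TCA cycle with a cytosolic/mitochondrial pyruvate
pair, methanol dissimilation (Metoh -> formaldehyde -> formate -> CO2)
and assimilation (dihydroxyacetone synthase: formaldehyde + Xul5P -> DHA
+ GA3P), trehalose cycling with a small secretion flux, the pyruvate
dehydrogenase bypass, alpha-ketoglutarate/glutamate and
oxaloacetate/aspartate exchanges, aspartate lyase, an unlabelled
mitochondrial pyruvate source/sink pair tied equal, and nine biomass
precursor drains. It has 37 carbon-pool metabolites and 79 fluxes
(reversible steps counted forward + backward). Seventeen constraints —
three measured rates (glucose uptake 0.71, methanol uptake 0.94, CER 2.03
mmol/gCDW/h), nine biomass drains, four symmetric 1:1 splits and the
pyruvate source/sink tie — leave 24 free fluxes (8 free net fluxes + 16
exchange fluxes). Of the 37 pools, 27 carry measured values on the
umol/gCDW scale of the study and 10 are estimation targets, for 34
parameters in total. The reaction naming (emp/tca/met/ppp/tre prefixes)
is best-effort; exact identities of the original model file are not
recoverable from the main text.

The reference flux distribution shipped with the package satisfies all
balances and constraints exactly and mirrors the headline physiology
(≈55% of the Glc6P supply to the oxidative PPP, ≈54% of methanol
dissimilated, trehalose recycling ≈1.5% of glucose uptake, 1.2 mmol/gCDW/h
unlabelled pyruvate exchange). It is a demonstration setting, not a
fitted result.

## Estimation

Measured fragments enter a weighted least-squares objective with the
study's error model: constant 2% relative standard deviation per
mass-isotopomer fraction, floored at 0.002 absolute so near-zero
fractions do not get unbounded weight (the floor value is a package
choice; the original description is ambiguous between sd and variance and
2% relative sd is the common reading in the field). Free net fluxes are
bounded box coordinates; exchange fluxes use the bounded transform
`exchange = beta/(1-beta)`, `beta in [0, 0.95]`, because unbounded
exchange fluxes destabilise fitting; unmeasured pools are estimated in
log10 within [1e-3, 50] umol/gCDW. Optimisation is multi-start bounded
trust-region least squares with seeded uniform starts; identical seeds
and configs give bit-identical results.

A fit is accepted when the weighted residual falls below the chi-square
95% quantile at dof = n_measurements - n_parameters (at study scale:
1600 fractions, 34 parameters, dof 1566, threshold 1659.2). Confidence
intervals come from linearised error propagation, cov = (J^T W J)^-1,
with the Jacobian recomputed at the optimum by central differences whose
step is scaled to the parameter box — the optimiser's internal
finite-difference steps are dominated by ODE-solver noise and would mask
structurally flat directions. Singular-value directions below an absolute
floor (2 weighted-residual units per unit parameter) are flagged
structurally unidentifiable and reported with infinite CIs rather than
pseudo-inverted away.

## Synthetic data

The generators reproduce the experiment's statistical structure: 20
sampling times from 5 s growing exponentially to 6 h
(`t_k = 5s * (6h/5s)^(k/19)`); independent Gaussian noise of 2% relative
sd per fraction, truncated at zero, each MID renormalised to sum 1 (the
original noise distribution is not stated; independence within an MID is
an assumption). Ground truths sample free fluxes uniformly in bounds,
complete them through the constraint null space, reject draws violating
irreversibility, and draw pools log-uniformly in 0.01-20 umol/gCDW, the
physiological window of the measured concentrations. Concentration tables
get lognormal replicate noise; rate tables are derived carbon- and
electron-balanced from the truth's boundary fluxes before noise.

Renormalising a noisy MID removes one degree of freedom per MID per time
point, so the residual of the true parameters on generated data follows
chi-square with approximately `n - n_MIDs * T` dof, not `n`; the
calibration test uses that reference. What passing these tests shows is
that the estimator is consistent and calibrated *under the generator's
assumptions*; real chromatography/MS data add correlated within-MID
errors, drift and fragment-specific biases that the generator does not
emulate.

## NET analysis

A reaction carrying flux must run downhill: `DrG' = DrG'0 + RT ln Q < 0`
in its flux direction (implemented as <= -1e-6 kJ/mol). In
log-concentration space these are linear constraints, so feasibility,
per-metabolite range tightening (min/max ln c), per-reaction attainable
DrG' intervals and extremal cofactor ratios are linear programs (HiGHS).
Infeasible systems are diagnosed by a minimum-slack LP naming the
violated reactions. Measured pools are converted to mM through the
specific cell volume of 1.7 ml/gCDW in a single lumped cytosolic
compartment (methanol reactions included); measured ranges are Student-t
80% confidence intervals of the replicate mean; unmeasured species
default to 1e-3 to 10 mM. Standard transformed Gibbs energies are inputs
per pH scenario (7.0/7.2/7.5 at ionic strength 0.15 M); the shipped table
is a synthetic stand-in with literature-scale values — NAD-coupled
dehydrogenases release one proton, so their DrG'0 falls by ~5.7 kJ/mol
per pH unit, which is what makes the minimum feasible NAD+/NADH ratio
decrease with increasing pH. With the shipped concentrations the
classical transketolase/transaldolase stoichiometry is infeasible exactly
at transaldolase, and the channelled variant
(Xul5P + Rib5P <-> Fru6P + E4P) restores feasibility; because the
non-oxidative PPP operates close to equilibrium, the package reports
per-reaction DrG' margins alongside the binary verdict.

## Balance accounting

Respiratory quotient CER/OUR; carbon recovery
`100 * (q_biomass + CER) / (6 |q_glc| + |q_metoh|)`. Rate reconciliation
projects the measured rate vector onto the carbon + degree-of-reduction
balance subspace by weighted least squares; the residual statistic
`h = r^T (E S E^T)^-1 r` is chi-square with rank(E) dof under the
no-gross-error hypothesis. The biomass elemental composition defaults to
CH1.761O0.636N0.143 (degree of reduction 4.06 per Cmol, NH3 reference)
and is configurable; with this default and the printed, rounded rate
table the test statistic lands marginally above the 95% bound — the
original analysis used its own measured composition.

Cofactor turnover is the stoichiometric dot product of per-reaction
coefficients with net fluxes; lumped reactions carry their components'
cofactors. NADH and FADH2 electrons are pooled for the theoretical oxygen
demand `(NADH + FADH2)/2` (one O per two electrons), reported also as a
percentage of the measured OUR; NADPH is never transhydrogenated into
NADH — imbalances are reported, not closed. ATP from oxidative
phosphorylation is `2 * (P/O) * qO2` with P/O = 1.48 mol ATP/mol O;
non-growth maintenance is the total minus a configurable
growth-associated demand (default 5.9 mmol ATP/gCDW/h, i.e. ~65 mmol
ATP/gCDW at dilution rate 0.09 1/h); a negative maintenance value is
flagged, never clamped.

## Known limitations

- The packaged network, pools, Gibbs energies and fragment list are
  synthetic stand-ins reconstructed from the published description, not
  the study's raw data files; quantitative flux maps fitted to them are
  demonstrations.
- The full 34-parameter fit of the packaged network is supported but
  computationally heavy (each objective evaluation integrates ~1100 stiff
  ODEs); the shipped analyses demonstrate estimation on small
  identifiable networks and validate the full network via residual and
  counting checks.
- Single lumped compartment; no peroxisomal pools; no tandem-MS or NMR
  positional data; natural-abundance correction assumes independent
  elemental isotope distributions and known ion formulas.
- Confidence intervals are linearised; strongly curved or
  boundary-constrained parameters (exchange fluxes near zero) are better
  served by profile likelihood, which is out of scope.
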