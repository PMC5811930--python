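# Methods

## Model

`gpcrbias` simulates a single receptor population that interconverts between
an inactive conformation R and `N*` active conformations R\*ʲ, binds one
ligand L, and couples `N^G` G proteins Gᶿ.  Every (j, θ) pair of active
state and G protein defines a cubic ternary complex: eight receptor species
(R, LR, R\*ʲ, LR\*ʲ, RGᶿ, LRGᶿ, R\*ʲGᶿ, LR\*ʲGᶿ) connected along three
reversible axes — ligand binding, activation, coupling — with dimensionless
cooperativity multipliers μʲθ (activation↔coupling), νᶿ (binding↔coupling)
and ζʲ (binding↔activation) scaling the doubly- and triply-modified edges.
Because each multiplier appears identically on the two paths around every
cube face, the reversible sub-network satisfies the thermodynamic cycle
conditions for *any* parameter values; the detailed-balance test exploits
this.

The active ternary complexes R\*ʲGᶿ and LR\*ʲGᶿ dissociate irreversibly
with rate kGTP₊ʲθ (ν₋ᶿ·kGTP₊ʲθ for the ligand-bound form), releasing
αGTPᶿ and βγᶿ.  The G-protein cycle closes through hydrolysis
(αGTP ⇌ αGDP, khyd±) and heterotrimer reassociation
(αGDP + βγ ⇌ G, kGRA±).  The readout of pathway activity is [αGTPᶿ](t).

The right-hand side is assembled as an explicit reaction network
(stoichiometry matrix × mass-action rate vector) with an analytic Jacobian;
directed reactions with zero rate constants are removed, so μ = 0 or
kGTP₊ = 0 entries delete reactions rather than contributing null terms.
Conservation of total receptor and of per-pathway α and βγ subunits holds
exactly in the vector field and is monitored as an integration-quality
check (observed drift ≲ 1e-11 relative over 10⁴ s at the default
tolerances).  The test suite verifies the network-generated derivatives
term-by-term against an independent, literal transcription of the
per-species balance equations, and against a separately hand-coded
single-cube system in the N\* = N^G = 1 limit.

State ordering is fixed and documented (R, LR, R\*ʲ blocks, LR\*ʲ blocks,
Gᶿ, RGᶿ, LRGᶿ, R\*ʲGᶿ, LR\*ʲGᶿ, αGTPᶿ, αGDPᶿ, βγᶿ, then L when the
ligand is dynamic), so state files are stable across versions.  Constant
ligand is the default operating mode — ligand is in vast excess over
receptor in the assays being emulated — with the ligand ODE available as
`ligand_mode="dynamic"` for completeness.

## Default parameters

Units are molar and seconds; no unit-conversion layer exists.  Defaults
(`model_core.default_parameters`):

| parameter | value | meaning |
|---|---|---|
| kL₊ / kL₋ | 1e5 M⁻¹s⁻¹ / 5e-3 s⁻¹ | ligand binding, K_D = 50 nM |
| kact₊ / kact₋ | 0.05 / 100 s⁻¹ | activation; K_act = 5e-4 (low constitutive activity) |
| kG₊ / kG₋ | 1e5 M⁻¹s⁻¹ / 1e-3 s⁻¹ | receptor–G coupling |
| kGTP₊ | 1 s⁻¹ (j = θ), 0 otherwise | nucleotide exchange |
| khyd₊ / khyd₋ | 1e-2 / 1e-8 s⁻¹ | hydrolysis |
| kGRA₊ / kGRA₋ | 1e5 M⁻¹s⁻¹ / 1.3e-4 s⁻¹ | heterotrimer reassociation |
| R_tot | 4.15e-9 M | total receptor |
| G_tot | 1e-8 M per pathway | total G protein |
| μ | 1 (j = θ), 0 otherwise | exclusive specificity |
| ν, ζ | 1 | neutral ligand; scenarios override |

Several of these magnitudes (kL₊, kact₊, khyd₋, kGRA₋, kGTP₊, R_tot) are
standard in the kinetic GPCR-cycle literature; the remainder were chosen
once, at physically reasonable magnitudes, so that the default system
expresses the full set of kinetic phenomena the model is meant to study,
and then frozen.  Two properties of the default regime matter:

1. **Committed coupling.**  kG₋ (1e-3 s⁻¹) is small compared with both the
   exchange rate kGTP₊ (1 s⁻¹) and the coupled-activation rate μ·kact₊
   (0.05 s⁻¹), so a receptor–G encounter usually proceeds to nucleotide
   exchange instead of dissociating.  Receptor-pool competition between
   pathways is then expressed directly in the αGTP responses: a pathway-1
   agonist that is neutral for pathway 2 visibly depresses αGTP², a
   balanced agonist on a strongly constitutive background inter-converts
   from agonist to apparent inverse agonist over time, and plateau CR
   curves can be non-monotonic.
2. **Slow cycle.**  Reassociation (kGRA₊·[βγ] ≈ 1e-4–1e-3 s⁻¹) is
   rate-limiting, so an agonist step produces the characteristic
   peak–plateau transient: a burst consumes the heterotrimer pool, then the
   response relaxes to a reassociation-limited steady state.  In this
   regime the *plateau* EC₅₀ carries the receptor-reserve shift when R_tot
   changes; the *peak* potency is binding-limited and nearly
   R_tot-invariant, which is why the receptor-number regression tests the
   EC₅₀ shift on the plateau feature and the maxima on both.

`gpcrbias.scenarios` freezes the named study conditions (dual agonist,
agonist/antagonist, agonist/inverse-agonist with kact₋² = 10, high
constitutive activity kact₋² = 1, and so on).  The bias-quantification
scenarios instead use a *reversible-coupling* variant (kG₋ = 1 s⁻¹): with
coupling equilibrated on the response timescale, a ligand's pathway-2
signalling scales with the product ν²ζ² of its coupling and activation
cooperativities — the structure the mechanistic alternative bias factor
assumes — whereas in the committed regime inactive-receptor capture makes
ν² nearly irrelevant at high ζ² and can even make weak-ν responses
non-monotonic.  Both regimes are honest corners of the same model; the
scenario modules simply assign each analysis the corner it was designed
for.

## Protocols and numerics

Pre-equilibration integrates the canonical initial condition (all receptor
free and inactive, all G protein heterotrimeric, no ligand) for 10⁸ s and
checks the residual max|dy/dt| against a steady tolerance (1e-22 M/s);
ligand addition is a parameter step at t = 0, not an impulse.  Integration
uses `scipy.integrate.solve_ivp` (LSODA, analytic Jacobian) with
rtol = 1e-10 and atol = 1e-20 M — tight because concentrations span roughly
1e-13–1e-8 M and conserved totals must drift by less than 1e-9 relative.
Peak and trough are located on the output grid and refined with a local
quadratic fit (ties resolve to the earliest time); plateau is the endpoint
value; traces that never leave the basal–endpoint envelope by more than a
relative tolerance are flagged monotone.  EC₅₀ extraction interpolates the
half-maximal crossing in log-concentration for monotone curves and reports
the interior-maximum location, flagged, for non-monotonic ones.
Concentration–response runs share one pre-equilibration across the ligand
grid (the basal state is ligand-independent), and response surfaces cache
the pre-equilibration whenever both varied parameters are ligand-only.

## Operational fitting and bias factors

The operational model is fitted in log₁₀(K_D), log₁₀(τ) space (bounds
log₁₀K_D ∈ [−12, −3], log₁₀τ ∈ [−4, 6]) with geometry-based multi-start
initialisation, on responses rescaled to order one (τ and K_D are invariant
to response rescaling; Emax and basal simply scale).  Near-flat curves
(range < 1% of basal) are rejected as unfittable rather than returning a
spurious τ.

A structural identifiability point drives the API: a *single* hyperbolic
curve determines only its top, EC₅₀ and basal — three observables for four
parameters — so with a freely fitted Emax, τ slides along a ridge and
log₁₀(τ/K_D) inherits an arbitrary offset of up to log₁₀(τ/(τ+1)).
`fit_operational` therefore accepts a fixed system maximum `emax`, and
`fit_operational_bank` fits a ligand bank against a shared per-pathway
maximum (1.05 × the largest response observed across the bank), the
standard convention that makes τ comparable across ligands.  All bias
factors in the package (equilibrium and dynamic) use bank fits.  In the
τ → ∞ limit only τ/K_D remains identifiable, which is all the transduction
coefficient needs.

Bias factors are ΔΔlog₁₀(τ/K_D) versus a reference ligand; by construction
they are exactly antisymmetric under pathway swap and additive along ligand
chains.  The mechanistic alternative score is
(kL₊/kL₋)·(ν¹ζ¹)/(ν²ζ²) normalised by the reference's value, with
equilibrium cooperativities ν = ν₊/ν₋, ζ = ζ₊/ζ₋.  On the nine-ligand bank
(ζ₊² ∈ {300, 100, 30} × ν₊² ∈ {1, 0.5, 0.25}, all products distinct,
reference the strongest pathway-2 agonist) the operational and alternative
bias factors agree in rank exactly and closely in magnitude.  Dynamic bias
fits the instantaneous CR curve at each requested time point,
independently per time point; the four-ligand kinetic-context bank contains
a deliberately near-degenerate pair (ζ₊² = 300 with ν₊² = 0.25, versus
ζ₊² = 65 with ν₊² = 1) whose rank order flips between 30 s and long-time
readouts.

## cAMP readout, PTX, and fitting

The endpoint readout integrates the *full* αGTP level from ligand addition
(t = 0) to t_end = 1800 s — basal signalling contributes to the integral;
the signals are not increments over basal.  C_s and C_i convert αGTP levels
to cAMP production-rate units and absorb the percent-normalisation
constants (the two are not separately identifiable); percent mode reports
100·signal/reference_signal with a configurable reference emulating a
maximal-stimulation control.  The same C_s applies to intact and
PTX-treated conditions.  PTX is modelled by zeroing exactly kG₊², kGTP₊²²
and kGRA₋², locking the Gi α subunit in its GDP-bound state; each condition
is pre-equilibrated under its own parameters, because PTX alters basal Gi
cycling.  In the synthetic-truth scenario the intact and PTX stimulatory
integrals agree within ~10% at saturating ligand, the residual gap being
Gi–Gs competition for the shared receptor pool.

The synthetic generator (ζ₊¹ = 15, ζ₊² = 500, kact₋ = 1000 s⁻¹, C_s = 2,
C_i = 1, reference 5e-7) produces the qualitative endpoint structure of
real Gi/Gs-switching receptors: a non-monotonic percent-inhibition curve
(peak ≈ 30%, downturn ≈ 20% of span at high concentration) and a monotonic
percent-stimulation curve (≈ 5% → 56%), with seeded additive Gaussian
noise.  What passing tests on these data do *not* show: the generator
emulates neither biological replicate structure, nor
concentration-dependent (heteroscedastic) assay noise, nor plate/batch
effects, so recovery results speak to algorithmic correctness rather than
to real-assay identifiability.

Endpoint fitting minimises the pooled squared error of both conditions
simultaneously over log₁₀-scaled free parameters.  The default free set
follows a one-rate-per-reversible-reaction policy — ligand cooperativities
ζ₊¹, ζ₊², ν₊¹, ν₊² plus C_s, C_i float; reverse rates and the disabled
cross states (μʲθ = kGTP₊ʲθ = 0, j ≠ θ) stay fixed.  The local stage is a
trust-region least-squares solve; an optional seeded differential-evolution
stage (off by default: a well-initialised local solve already reaches the
global basin in the round-trip problems, and the global stage multiplies
cost by ~50×) explores around the local optimum, followed by a polish.
Warm-starting from a previous ligand's fit is supported via the `initial`
mapping.  Zero-noise round trips recover the generating curves to ~1e-10
relative; fits are bit-for-bit reproducible under a fixed seed.

## Known limitations

* Single compartment; no receptor oligomerisation, trafficking, spatial
  effects, or stochastic (SSA) simulation; no SBML import/export.
* The operational model is used in its basal-aware hyperbolic form; no Hill
  coefficient.
* Problem sizes in the test and acceptance runs (ligand grids of 8–19
  points, banks of 4–9 ligands, 50-draw recovery studies) are desk-scale
  choices; all scale linearly if enlarged.
* The committed-coupling default regime was chosen to make the model's
  full phenomenology observable with one parameter set; systems with fast
  G-protein dissociation behave like the reversible variant, where some
  receptor-competition phenomena (e.g. apparent inverse agonism of a
  neutral ligand) are much weaker.
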