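# gpcrbias

Dynamic modelling and quantification of **biased agonism** at a G
protein-coupled receptor (GPCR).

Many GPCRs can adopt more than one active conformation and couple more than
one G protein, so a single ligand at a single receptor can drive several
downstream pathways with different strengths — a phenomenon with direct
consequences for drug discovery, where one pathway may be therapeutic and
another a side effect.  `gpcrbias` is a research tool for pharmacologists and
modellers who want to simulate and quantify this behaviour *dynamically*
rather than only at equilibrium.

## The model

The core is a mass-action ODE system for a receptor with `N*` active
conformations R\*ʲ and `N^G` G proteins Gᶿ.  Each (j, θ) pair forms a **cubic
ternary complex**: the cube's axes are ligand binding (K_L), receptor
activation (K_actʲ) and G-protein coupling (K_Gᶿ), and dimensionless
cooperativity factors couple its faces —

* **μʲθ** — preference of Gᶿ for R\*ʲ over R,
* **νᶿ** — preference of the ligand for the Gᶿ-coupled receptor,
* **ζʲ** — preference of the ligand for R\*ʲ over R (ζ > 1 agonist,
  ζ = 1 neutral antagonist, ζ < 1 inverse agonist).

Ternary complexes R\*ʲGᶿ dissociate irreversibly (GDP→GTP exchange,
kGTP₊ʲθ), feeding the G-protein cycle

    alphaGTP_theta  --hydrolysis-->  alphaGDP_theta  --(+ betagamma)-->  G_theta

and the per-pathway readout is [αGTPᶿ](t).  For `N* = N^G = 2` with constant
ligand this is a 26-dimensional ODE system (18 receptor species + 8 free
G-protein species).  Units are molar and seconds throughout.

On top of the simulator the package provides:

* **Protocols** — ligand-free pre-equilibration (10⁸ s), time courses,
  peak/trough/plateau feature extraction, concentration–response (CR)
  curves, response surfaces.
* **Bias quantification** — operational-model fits
  `E([A]) = basal + (Emax − basal)·τ[A]/(K_D + (τ+1)[A])`, transduction
  coefficients `T = log₁₀(τ/K_D)`, ΔΔlog₁₀ bias factors versus a reference
  ligand, a mechanistic alternative bias factor built from
  `(kL₊/kL₋)·(ν¹ζ¹/ν²ζ²)`, and time-resolved (dynamic) bias factors.
* **Functional cAMP readout** — endpoint signals
  `signal_stim(t) = ∫₀ᵗ C_s·αGTP_s dt` and
  `signal_inhib(t) = ∫₀ᵗ (C_i·αGTP_i − C_s·αGTP_s) dt` modelling functional
  antagonism between Gs- and Gi-driven cAMP production, with an in-silico
  pertussis-toxin (PTX) intervention that uncouples Gi.
* **Fitting** — a synthetic-endpoint-data generator and simultaneous
  least-squares estimation from intact + PTX percent-of-reference CR data
  (trust-region local stage plus optional seeded differential evolution).

## Worked example

A ligand that agonises both pathways, more strongly pathway 1
(ζ₊¹ = 1000, ζ₊² = 200), added at 1 μM after pre-equilibration:

```python
import numpy as np
from gpcrbias import pre_equilibrate, run_timecourse, extract_features
from gpcrbias.scenarios import TWO_PATHWAY, dual_agonist

spec = TWO_PATHWAY                     # N* = 2 active states, 2 G proteins
params = dual_agonist()                # zeta+1 = 1000, zeta+2 = 200
basal = pre_equilibrate(spec, params)  # ligand-free steady state
print(f"basal [aGTP1] = {basal['aGTP1']:.3e} M")
traj = run_timecourse(spec, params, basal, L=1e-6)
for pw in (1, 2):
    ft = extract_features(traj, pw)
    print(f"pathway {pw}: peak {ft.peak:.3e} M at {ft.peak_time:.1f} s, "
          f"plateau {ft.plateau:.3e} M")
```

prints

```
basal [aGTP1] = 4.421e-11 M
pathway 1: peak 7.732e-10 M at 29.2 s, plateau 1.886e-10 M
pathway 2: peak 6.903e-10 M at 43.8 s, plateau 1.492e-10 M
```

The agonist step releases a burst of activated α subunits that overshoots
(peak ≈ 0.77 nM on the stronger pathway, reached within half a minute) and
then relaxes to a lower plateau as the heterotrimeric G-protein pool
depletes; the weaker pathway responds later and lower.  Raising the ligand
concentration shifts both peaks earlier — one of several kinetic signatures
(apparent inverse agonism of a neutral ligand, trough-time growth under an
inverse agonist, agonist-to-inverse-agonist inter-conversion, non-monotonic
CR curves) that `gpcrbias.scenarios` packages as ready-made study
conditions.

The same system is available from the shell:

```bash
gpcrbias timecourse --config examples/two_pathway.yaml -L 1e-6 --out out/
gpcrbias crcurve    --config examples/two_pathway.yaml --feature plateau --out out/
gpcrbias synth-data --config examples/two_pathway.yaml --seed 1 --out out/
```

Every run writes unit-annotated CSVs plus a checksummed manifest and a
provenance record (config hash, version, seed).

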