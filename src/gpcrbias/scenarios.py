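"""Canonical study conditions: named parameterisations of the two-pathway system.

Each scenario fixes the ligand efficacy pattern (and, where the phenomenon
requires it, the receptor/G-cycle regime) that produces one of the model's
characteristic behaviours.  Two coupling regimes recur:

* the *committed* default regime (``default_parameters``): receptor-G
  engagement is slowly reversible relative to nucleotide exchange, so
  receptor-pool competition between pathways shows up directly in the
  alphaGTP responses (apparent inverse agonism of a neutral ligand, dynamic
  agonist-to-inverse-agonist inter-conversion, non-monotonic
  concentration-response curves);
* the *reversible* regime (``kG- = 1 s^-1``) used for bias quantification,
  where G-coupling equilibrates and a ligand's pathway-2 signalling scales
  with the product of its coupling and activation cooperativities
  (nu2 * zeta2), the structure the mechanistic alternative bias factor
  assumes.

All scenarios use the two-active-state, two-G-protein structure with
exclusive receptor-state/G-protein specificity.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .functional_readout import ReadoutParams
from .model_core import ModelSpec, ParameterSet, default_parameters

__all__ = [
    "TWO_PATHWAY", "dual_agonist", "agonist_antagonist", "isolated_pathway",
    "agonist_inverse_agonist", "high_constitutive_dual_agonist",
    "nonmonotonic_cr", "bias_reference_parameters", "bias_ligand_bank",
    "kinetic_context_bank", "functional_antagonism_truth",
]

TWO_PATHWAY = ModelSpec(n_active=2, n_gprot=2, ligand_mode="constant")


def dual_agonist(zeta1: float = 1000.0, zeta2: float = 200.0) -> ParameterSet:
    """Agonist for both pathways, stronger for pathway 1."""
    p = default_parameters(TWO_PATHWAY)
    p.zeta_plus[:] = [zeta1, zeta2]
    return p


def agonist_antagonist() -> ParameterSet:
    """Pathway-1 agonist (zeta1 = 1000) that is neutral for pathway 2.

    In the intact two-pathway system the neutral ligand shows an apparent
    inverse-agonist effect on pathway 2 because pathway-1 activation drains
    the shared receptor pool.
    """
    p = default_parameters(TWO_PATHWAY)
    p.zeta_plus[:] = [1000.0, 1.0]
    return p


def isolated_pathway() -> ParameterSet:
    """Pathway 2 isolated by disabling pathway-1 activation (kact+1 = 0).

    A neutral ligand (zeta2 = nu = 1) then has a true null effect: alphaGTP2
    stays constant after ligand addition.
    """
    p = default_parameters(TWO_PATHWAY)
    p.kact_plus[0] = 0.0
    return p


def agonist_inverse_agonist() -> ParameterSet:
    """Pathway-1 agonist / pathway-2 inverse agonist with elevated pathway-2
    constitutive activity (zeta1 = 100, zeta2 = 0.01, kact-2 = 10), the
    regime in which alphaGTP2 undershoots below basal with a trough time
    that grows with ligand concentration."""
    p = default_parameters(TWO_PATHWAY)
    p.zeta_plus[:] = [100.0, 0.01]
    p.kact_minus[1] = 10.0
    return p


def high_constitutive_dual_agonist() -> ParameterSet:
    """Balanced dual agonist (zeta = 100 both) with strongly constitutive
    pathway 2 (kact-2 = 1): shows dynamic inter-conversion, with alphaGTP1
    rising above basal early and settling below basal at long times."""
    p = default_parameters(TWO_PATHWAY)
    p.zeta_plus[:] = [100.0, 100.0]
    p.kact_minus[1] = 1.0
    return p


def nonmonotonic_cr() -> ParameterSet:
    """Dual agonist (zeta1 = 1000, zeta2 = 100) with high pathway-2
    constitutive activity (kact-2 = 1): the plateau alphaGTP1
    concentration-response curve is non-monotonic in ligand concentration."""
    p = default_parameters(TWO_PATHWAY)
    p.zeta_plus[:] = [1000.0, 100.0]
    p.kact_minus[1] = 1.0
    return p


def bias_reference_parameters() -> ParameterSet:
    """Reversible-coupling system used for operational bias quantification.

    kG- is raised to 1 s^-1 so that G coupling equilibrates on the response
    timescale; pathway-1 efficacy is fixed at zeta1 = 30 for every ligand in
    the bank."""
    p = default_parameters(TWO_PATHWAY)
    p.kG_minus[:] = 1.0
    p.zeta_plus[:] = [30.0, 300.0]
    return p


def bias_ligand_bank() -> Tuple[Dict[str, ParameterSet], str]:
    """Nine-ligand bank varying pathway-2 cooperativities, plus reference.

    Ligands share pathway-1 parameters and differ in zeta+2 (300, 100, 30)
    crossed with nu+2 (1, 0.5, 0.25); all nu2*zeta2 products are distinct, so
    the mechanistic alternative bias factor gives a strict rank order.  The
    reference is ligand 1, the strongest pathway-2 agonist (least
    pathway-1-biased).
    """
    bank: Dict[str, ParameterSet] = {}
    i = 1
    for z2 in (300.0, 100.0, 30.0):
        for nu2 in (1.0, 0.5, 0.25):
            p = bias_reference_parameters()
            p.zeta_plus[1] = z2
            p.nu_plus[1] = nu2
            bank[f"ligand{i}"] = p
            i += 1
    return bank, "ligand1"


def kinetic_context_bank() -> Tuple[Dict[str, ParameterSet], str]:
    """Four-ligand bank whose bias rank order changes with readout time.

    Ligand A (zeta2 = 300, nu2 = 0.25) and ligand B (zeta2 = 65, nu2 = 1)
    have nearly equal long-time bias, but A's pathway-2 signalling relies on
    the coupling cooperativity and carries a larger early transient, so A
    ranks below B early and above B late.  Ligand C (zeta2 = 30) is a stable
    strongly-biased comparator; the reference is the unbiased strong
    pathway-2 agonist.
    """
    bank = {}
    for name, z2, nu2 in (("reference", 300.0, 1.0), ("ligandA", 300.0, 0.25),
                          ("ligandB", 65.0, 1.0), ("ligandC", 30.0, 1.0)):
        p = bias_reference_parameters()
        p.zeta_plus[1] = z2
        p.nu_plus[1] = nu2
        bank[name] = p
    return bank, "reference"


def functional_antagonism_truth() -> Tuple[ParameterSet, ReadoutParams]:
    """Generating conditions for synthetic endpoint cAMP data.

    A single ligand agonises both pathways of a Gs (pathway 1) / Gi
    (pathway 2) system with low constitutive activity (kact- = 1000 s^-1),
    weakly for Gs (zeta1 = 15) and strongly for Gi (zeta2 = 500), so the
    inhibitory signal engages at lower concentrations than the stimulatory
    one.  With readout constants C_s = 2, C_i = 1 the intact-cell inhibition
    endpoint is non-monotonic (peak near 30% with a clear downturn at high
    concentration) while the PTX-cell stimulation endpoint rises
    monotonically to roughly 56%.  Signals are reported as percent of a
    fixed maximal-stimulation reference (5e-7 response units).
    """
    p = default_parameters(TWO_PATHWAY)
    p.zeta_plus[:] = [15.0, 500.0]
    p.kact_minus[:] = 1000.0
    rp = ReadoutParams(C_s=2.0, C_i=1.0, t_end=1800.0,
                       normalisation="percent-of-reference",
                       reference_signal=5e-7)
    return p, rp
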