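"""Downstream cAMP readout via functional antagonism, with the PTX intervention.

Pathway 1 is the stimulatory (Gs) pathway and pathway 2 the inhibitory (Gi)
pathway.  With cAMP degradation blocked, the cAMP production rate is taken
proportional to the alphaGTP stimuli, so endpoint signals are running
integrals of the alphaGTP levels:

    signal_stim(t)  = int_0^t C_s * [aGTP_s](t') dt'
    signal_inhib(t) = int_0^t ( C_i * [aGTP_i](t') - C_s * [aGTP_s](t') ) dt'

Integration starts at ligand addition (t = 0) and integrates the full
alphaGTP level, basal included — not the increment over basal.  Pertussis
toxin (PTX) pre-treatment uncouples Gi: it is modelled by zeroing the Gi
coupling rate, the matched Gi GDP/GTP-exchange rate, and the Gi heterotrimer
dissociation rate, which locks the Gi alpha subunit in its GDP-bound state.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.integrate import trapezoid

from .model_core import ParameterSet
from .simulation import Trajectory

__all__ = ["ReadoutParams", "apply_ptx", "signal_stim", "signal_inhib"]


@dataclass
class ReadoutParams:
    """Scaling constants and endpoint settings for the cAMP readout.

    ``C_s`` and ``C_i`` convert alphaGTP levels (M) into cAMP production
    rates (response units per second); they fold in any percent-normalisation
    constants and are not separately identifiable from them.  ``t_end``
    follows the endpoint-assay convention of 1800 s.  In
    ``percent-of-reference`` mode, signals are reported as
    100 * signal / reference_signal, emulating percent-of-maximal-stimulation
    readouts; ``reference_signal`` is a configurable constant of the
    synthetic-data pipeline.
    """

    C_s: float = 1.0
    C_i: float = 1.0
    t_end: float = 1800.0
    normalisation: str = "raw"            # "raw" | "percent-of-reference"
    reference_signal: float = 1.0

    def __post_init__(self) -> None:
        if self.C_s < 0 or self.C_i < 0:
            raise ValueError("C_s and C_i must be non-negative")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.normalisation not in ("raw", "percent-of-reference"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")

    def normalise(self, signal: float) -> float:
        if self.normalisation == "percent-of-reference":
            return 100.0 * signal / self.reference_signal
        return signal


def apply_ptx(params: ParameterSet, gi_pathway: int = 2) -> ParameterSet:
    """Return a copy of ``params`` with the Gi pathway uncoupled (PTX).

    Zeroes exactly kG+^theta, kGTP+^{theta,theta} and kGRA-^theta for
    theta = ``gi_pathway``; everything else is untouched.  Idempotent.
    """
    t = gi_pathway - 1
    if not 0 <= t < len(params.kG_plus):
        raise ValueError(f"gi_pathway {gi_pathway} out of range")
    out = params.copy()
    out.kG_plus[t] = 0.0
    if t < out.kGTP_plus.shape[0]:
        out.kGTP_plus[t, t] = 0.0
    out.kGRA_minus[t] = 0.0
    return out


def _integral(traj: Trajectory, values: np.ndarray, t_end: float) -> float:
    t = traj.t
    if t[-1] < t_end * (1 - 1e-9):
        raise ValueError(f"trajectory ends at {t[-1]:.6g} s, before t_end = {t_end:.6g} s")
    mask = t <= t_end * (1 + 1e-12)
    tt, vv = t[mask], values[mask]
    if tt[-1] < t_end:
        # close the window exactly at t_end by linear interpolation
        v_end = np.interp(t_end, t, values)
        tt = np.append(tt, t_end)
        vv = np.append(vv, v_end)
    return float(trapezoid(vv, tt))


def signal_stim(traj: Trajectory, rp: ReadoutParams,
                stim_pathway: int = 1) -> float:
    """Endpoint stimulation signal: C_s * integral of aGTP_s over [0, t_end]."""
    vals = rp.C_s * traj.alpha_gtp(stim_pathway)
    return rp.normalise(_integral(traj, vals, rp.t_end))


def signal_inhib(traj: Trajectory, rp: ReadoutParams,
                 stim_pathway: int = 1, inhib_pathway: int = 2) -> float:
    """Endpoint inhibition signal: integral of C_i*aGTP_i - C_s*aGTP_s.

    May be non-monotonic in ligand concentration: a ligand engaging both
    pathways raises the subtracted stimulatory term at high concentrations,
    producing the characteristic downturn.
    """
    vals = rp.C_i * traj.alpha_gtp(inhib_pathway) - rp.C_s * traj.alpha_gtp(stim_pathway)
    return rp.normalise(_integral(traj, vals, rp.t_end))
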