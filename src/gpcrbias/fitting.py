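"""Parameter estimation from intact + PTX endpoint concentration-response data,
and the synthetic-data generator that emulates endpoint cAMP assays.

The experimental design emulated here measures, at a single endpoint time,
(i) percent inhibition of cAMP in intact cells (both Gs and Gi signalling)
and (ii) percent stimulation of cAMP in PTX-treated cells (Gi uncoupled),
each across a ligand concentration ladder and normalised to a maximal-
stimulation reference.  Both conditions are fitted simultaneously by
least squares on the pooled residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from .functional_readout import ReadoutParams, apply_ptx, signal_inhib, signal_stim
from .model_core import ModelSpec, ParameterSet, get_param, set_param
from .simulation import Protocol, pre_equilibrate, run_timecourse

__all__ = [
    "EndpointDataset", "FitConfig", "FitResult",
    "simulate_endpoints", "generate_synthetic_dataset", "fit_endpoints",
]


@dataclass
class EndpointDataset:
    """Endpoint CR data for one ligand under intact and PTX conditions."""

    ligand: str
    concentrations: np.ndarray          # M, increasing
    inhibition: np.ndarray              # intact cells, percent inhibition
    stimulation: np.ndarray             # PTX cells, percent stimulation
    noise_sd: float = 0.0
    t_end: float = 1800.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        self.stimulation = np.asarray(self.stimulation, dtype=float)
        n = len(self.concentrations)
        if len(self.inhibition) != n or len(self.stimulation) != n:
            raise ValueError("per-condition response arrays must match the concentration grid")
        if np.any(self.concentrations <= 0) or np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, resp in (("intact", self.inhibition), ("ptx", self.stimulation)):
            for c, r in zip(self.concentrations, resp):
                rows.append({"concentration_M": c, "response": r,
                             "condition": cond, "ligand": self.ligand})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, t_end: float = 1800.0) -> "EndpointDataset":
        lig = str(df["ligand"].iloc[0])
        intact = df[df["condition"] == "intact"].sort_values("concentration_M")
        ptx = df[df["condition"] == "ptx"].sort_values("concentration_M")
        return cls(ligand=lig,
                   concentrations=intact["concentration_M"].to_numpy(),
                   inhibition=intact["response"].to_numpy(),
                   stimulation=ptx["response"].to_numpy(),
                   t_end=t_end)


@dataclass
class FitConfig:
    """Free/fixed parameter layout and optimiser settings.

    ``free_params`` names model parameters (``set_param`` syntax, e.g.
    ``"zeta_plus[1]"``) and/or the readout constants ``"C_s"`` / ``"C_i"``.
    The default free set follows the one-rate-per-reversible-reaction policy:
    reverse rates stay fixed and the ligand-specific forward cooperativities
    float, together with the readout scalings.  Bounds are in log10 space.
    The global stage is a seeded differential-evolution search around the
    local optimum; its budget defaults to 0 (off) because the local stage
    already solves well-initialised problems — raise ``global_maxiter`` for
    rugged landscapes.
    """

    free_params: Tuple[str, ...] = ("zeta_plus[1]", "zeta_plus[2]",
                                    "nu_plus[1]", "nu_plus[2]", "C_s", "C_i")
    fixed_params: Dict[str, float] = field(default_factory=dict)
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    default_bounds: Tuple[float, float] = (-4.0, 6.0)
    seed: int = 0
    global_maxiter: int = 0
    global_popsize: int = 8
    local_max_nfev: int = 400
    local_xtol: float = 1e-10
    local_ftol: float = 1e-12

    def bound_for(self, name: str) -> Tuple[float, float]:
        return self.bounds.get(name, self.default_bounds)


@dataclass
class FitResult:
    params: ParameterSet
    readout: ReadoutParams
    free_values: Dict[str, float]
    sse: float
    residuals: np.ndarray
    n_evaluations: int
    converged: bool
    report: str = ""


def simulate_endpoints(spec: ModelSpec, params: ParameterSet, rp: ReadoutParams,
                       L_grid: Sequence[float],
                       protocol: Optional[Protocol] = None,
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Endpoint (stimulation, inhibition) CR vectors over ``L_grid``.

    The intact system is pre-equilibrated ligand-free and, per concentration,
    integrated to ``rp.t_end`` to yield the inhibition signal; the PTX system
    is pre-equilibrated under its own (PTX-modified) parameters — PTX alters
    basal Gi cycling, so the two conditions have distinct basal states — and
    yields the stimulation signal.
    """
    protocol = protocol or Protocol(post_ligand_time=rp.t_end, n_points=241)
    L_grid = np.asarray(L_grid, dtype=float)
    grid = np.linspace(0.0, rp.t_end, protocol.n_points)

    basal_intact = pre_equilibrate(spec, params, protocol)
    params_ptx = apply_ptx(params)
    basal_ptx = pre_equilibrate(spec, params_ptx, protocol)

    stim = np.empty(len(L_grid))
    inhib = np.empty(len(L_grid))
    for i, L in enumerate(L_grid):
        traj_i = run_timecourse(spec, params, basal_intact, L, grid=grid,
                                protocol=protocol)
        inhib[i] = signal_inhib(traj_i, rp)
        traj_p = run_timecourse(spec, params_ptx, basal_ptx, L, grid=grid,
                                protocol=protocol)
        stim[i] = signal_stim(traj_p, rp)
    return stim, inhib


def generate_synthetic_dataset(spec: ModelSpec, true_params: ParameterSet,
                               rp: ReadoutParams, L_grid: Sequence[float],
                               noise_sd: float = 0.0, seed: int = 0,
                               ligand: str = "synthetic",
                               protocol: Optional[Protocol] = None,
                               ) -> EndpointDataset:
    """Simulated endpoint dataset with additive Gaussian noise (seeded).

    Runs :func:`simulate_endpoints`, applies the readout normalisation
    (typically percent-of-reference), and adds independent N(0, noise_sd)
    noise to every point.  With ``noise_sd = 0`` the output is exactly the
    normalised simulation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    stim, inhib = simulate_endpoints(spec, true_params, rp, L_grid, protocol)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        stim = stim + rng.normal(0.0, noise_sd, size=len(stim))
        inhib = inhib + rng.normal(0.0, noise_sd, size=len(inhib))
    return EndpointDataset(ligand=ligand, concentrations=np.asarray(L_grid, float),
                           inhibition=inhib, stimulation=stim,
                           noise_sd=noise_sd, t_end=rp.t_end)


def _apply_free(spec: ModelSpec, base_params: ParameterSet, base_rp: ReadoutParams,
                cfg: FitConfig, x_log10: np.ndarray,
                ) -> Tuple[ParameterSet, ReadoutParams]:
    p = base_params.copy()
    rp = ReadoutParams(C_s=base_rp.C_s, C_i=base_rp.C_i, t_end=base_rp.t_end,
                       normalisation=base_rp.normalisation,
                       reference_signal=base_rp.reference_signal)
    for name, val in cfg.fixed_params.items():
        if name == "C_s":
            rp.C_s = val
        elif name == "C_i":
            rp.C_i = val
        else:
            set_param(p, name, val)
    for name, lx in zip(cfg.free_params, x_log10):
        v = 10.0 ** lx
        if name == "C_s":
            rp.C_s = v
        elif name == "C_i":
            rp.C_i = v
        else:
            set_param(p, name, v)
    return p, rp


def fit_endpoints(spec: ModelSpec, data: EndpointDataset, cfg: FitConfig,
                  base_params: ParameterSet, base_rp: ReadoutParams,
                  initial: Optional[Mapping[str, float]] = None,
                  protocol: Optional[Protocol] = None) -> FitResult:
    """Simultaneous least-squares fit to intact + PTX endpoint curves.

    Two-stage optimisation: a trust-region local refinement
    (``scipy.optimize.least_squares``, TRF) from the initial guess, optionally
    followed by a seeded differential-evolution global search around the best
    point and a final local polish.  Free parameters are optimised in log10
    space.  ``initial`` maps free-parameter names to linear-scale starting
    values (e.g. a previous ligand's fit, for warm starting); unnamed free
    parameters start at the base parameter set's current value.

    Returns the best-fitting parameter set, SSE, per-point residuals and a
    convergence report.  Raises ``RuntimeError`` with best-so-far diagnostics
    if no start produces a finite objective.
    """
    protocol = protocol or Protocol(post_ligand_time=data.t_end, n_points=241)
    target = np.concatenate([data.stimulation, data.inhibition])
    n_eval = [0]

    def residuals(x_log10: np.ndarray) -> np.ndarray:
        n_eval[0] += 1
        try:
            p, rp = _apply_free(spec, base_params, base_rp, cfg, x_log10)
            stim, inhib = simulate_endpoints(spec, p, rp, data.concentrations,
                                             protocol)
            return np.concatenate([stim, inhib]) - target
        except Exception:
            return np.full(len(target), 1e6)

    # starting point in log10 space
    x0 = []
    for name in cfg.free_params:
        if initial and name in initial:
            v = float(initial[name])
        elif name == "C_s":
            v = base_rp.C_s
        elif name == "C_i":
            v = base_rp.C_i
        else:
            v = get_param(base_params, name)
        lo, hi = cfg.bound_for(name)
        x0.append(float(np.clip(np.log10(max(v, 1e-300)), lo, hi)))
    x0 = np.array(x0)
    lb = np.array([cfg.bound_for(n)[0] for n in cfg.free_params])
    ub = np.array([cfg.bound_for(n)[1] for n in cfg.free_params])

    local = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                          max_nfev=cfg.local_max_nfev, xtol=cfg.local_xtol,
                          ftol=cfg.local_ftol)
    best_x, best_sse = local.x, float(np.sum(local.fun**2))
    converged = bool(local.status > 0)

    if cfg.global_maxiter > 0:
        def objective(x):
            return float(np.sum(residuals(x)**2))
        de = differential_evolution(
            objective, bounds=list(zip(lb, ub)), seed=cfg.seed,
            maxiter=cfg.global_maxiter, popsize=cfg.global_popsize,
            init="sobol", x0=best_x, polish=False, tol=1e-12)
        if de.fun < best_sse:
            polish = least_squares(residuals, de.x, bounds=(lb, ub), method="trf",
                                   max_nfev=cfg.local_max_nfev)
            if float(np.sum(polish.fun**2)) < de.fun:
                best_x, best_sse = polish.x, float(np.sum(polish.fun**2))
            else:
                best_x, best_sse = de.x, float(de.fun)
            converged = True

    res = residuals(best_x)
    best_sse = float(np.sum(res**2))
    if not np.all(np.isfinite(res)) or best_sse >= 1e11:
        raise RuntimeError(
            f"endpoint fit failed: best SSE {best_sse:.3g} after {n_eval[0]} "
            f"evaluations; best point (log10) {dict(zip(cfg.free_params, best_x))}")
    p_best, rp_best = _apply_free(spec, base_params, base_rp, cfg, best_x)
    free_vals = {n: float(10.0 ** x) for n, x in zip(cfg.free_params, best_x)}
    report = (f"free={free_vals} sse={best_sse:.6g} n_eval={n_eval[0]} "
              f"local_status={local.status} global={'on' if cfg.global_maxiter else 'off'}")
    return FitResult(params=p_best, readout=rp_best, free_values=free_vals,
                     sse=best_sse, residuals=res, n_evaluations=n_eval[0],
                     converged=converged, report=report)
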