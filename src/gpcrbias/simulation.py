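"""Simulation protocols: pre-equilibration, time courses, features, CR curves, surfaces.

The standard protocol mirrors routine signalling experiments in silico: the
system is first integrated ligand-free for a long time (1e8 s by default) so
that constitutive activity reaches its steady state, then ligand is stepped
to the test concentration at t = 0 and the response integrated forward.  The
per-pathway readout is [alphaGTP_theta](t).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    LIGAND_PARAM_NAMES,
    MassActionRHS,
    ModelSpec,
    ParameterSet,
    SpeciesIndex,
    StateVector,
    build_rhs,
    conservation_totals,
    get_param,
    initial_state,
    set_param,
)

__all__ = [
    "Protocol", "Trajectory", "TimecourseFeatures", "CRCurve",
    "pre_equilibrate", "run_timecourse", "extract_features",
    "concentration_response", "response_surface", "estimate_ec50",
    "default_time_grid",
]


@dataclass
class Protocol:
    """Integration protocol settings.

    ``pre_equilibration_time`` follows the ligand-free spin-up convention of
    1e8 s; ``steady_tol`` is the max-|dy/dt| residual (M/s) below which the
    basal state is accepted.  Tolerances default to rtol 1e-10 / atol 1e-20 M,
    tight because concentrations span roughly 1e-13..1e-8 M and conserved
    totals are expected to drift by less than 1e-9 relative.
    """

    pre_equilibration_time: float = 1e8
    post_ligand_time: float = 3600.0
    n_points: int = 400
    grid: str = "linear"            # "linear" | "log"
    t_min: float = 1e-2             # first output time for log grids
    rtol: float = 1e-10
    atol: float = 1e-20
    method: str = "LSODA"
    steady_tol: float = 1e-22

    def __post_init__(self) -> None:
        if self.pre_equilibration_time <= 0 or self.post_ligand_time <= 0:
            raise ValueError("protocol times must be positive")
        if self.grid not in ("linear", "log"):
            raise ValueError("grid must be 'linear' or 'log'")

    def time_grid(self) -> np.ndarray:
        if self.grid == "log":
            g = np.geomspace(self.t_min, self.post_ligand_time, self.n_points - 1)
            return np.concatenate([[0.0], g])
        return np.linspace(0.0, self.post_ligand_time, self.n_points)


def default_time_grid(t_end: float = 3600.0, n: int = 400) -> np.ndarray:
    return np.linspace(0.0, t_end, n)


@dataclass
class Trajectory:
    """One simulated time course: output grid, concentration matrix, provenance."""

    t: np.ndarray                    # (n_t,) seconds, t = 0 at ligand addition
    y: np.ndarray                    # (n_t, n_species) molar
    species: SpeciesIndex
    ligand: float = 0.0
    provenance: str = ""

    def series(self, name: str) -> np.ndarray:
        return self.y[:, self.species[name]]

    def alpha_gtp(self, pathway: int) -> np.ndarray:
        return self.series(f"aGTP{pathway}")

    def state_at(self, i: int) -> StateVector:
        return StateVector(y=self.y[i].copy(), time=float(self.t[i]), species=self.species)


@dataclass
class TimecourseFeatures:
    """Summary features of one alphaGTP trace over the post-ligand window."""

    basal: float
    peak: float
    peak_time: float
    trough: float
    trough_time: float
    plateau: float
    monotone: bool


@dataclass
class CRCurve:
    """Concentration-response: one scalar feature per ligand concentration."""

    concentrations: np.ndarray
    response: np.ndarray
    feature: str = "plateau"
    pathway: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.shape != self.response.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


def _params_hash(params: ParameterSet) -> str:
    h = hashlib.sha256()
    for f in ("kL_plus", "kL_minus", "kact_plus", "kact_minus", "kG_plus", "kG_minus",
              "mu_plus", "mu_minus", "nu_plus", "nu_minus", "zeta_plus", "zeta_minus",
              "kGTP_plus", "khyd_plus", "khyd_minus", "kGRA_plus", "kGRA_minus",
              "R_tot", "G_tot", "L_conc"):
        h.update(np.asarray(getattr(params, f), dtype=float).tobytes())
    return h.hexdigest()[:16]


def _integrate(rhs: MassActionRHS, y0: np.ndarray, t_span: Tuple[float, float],
               t_eval: Optional[np.ndarray], protocol: Protocol):
    sol = solve_ivp(rhs, t_span, y0, method=protocol.method, jac=rhs.jac,
                    t_eval=t_eval, rtol=protocol.rtol, atol=protocol.atol)
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message} (the system is stiff; consider "
            f"method='BDF' or looser tolerances)")
    return sol


def pre_equilibrate(spec: ModelSpec, params: ParameterSet,
                    protocol: Optional[Protocol] = None) -> StateVector:
    """Ligand-free spin-up to the basal steady state.

    Integrates from the canonical initial condition (all receptor free and
    inactive, all G protein heterotrimeric) with [L] = 0 for
    ``pre_equilibration_time`` seconds, and warns if the RHS residual at the
    end exceeds ``steady_tol``.
    """
    protocol = protocol or Protocol()
    rhs = build_rhs(spec, params)
    rhs.ligand = 0.0
    s0 = initial_state(spec, params)
    y0 = s0.y.copy()
    if spec.ligand_mode == "dynamic":
        y0[rhs.species["L"]] = 0.0
    sol = _integrate(rhs, y0, (0.0, protocol.pre_equilibration_time), None, protocol)
    y_end = sol.y[:, -1]
    resid = float(np.max(np.abs(rhs(0.0, y_end))))
    if resid > protocol.steady_tol:
        warnings.warn(
            f"pre-equilibration residual max|dy/dt| = {resid:.3e} M/s exceeds "
            f"steady tolerance {protocol.steady_tol:.1e}", RuntimeWarning)
    return StateVector(y=y_end, time=0.0, species=rhs.species)


def run_timecourse(spec: ModelSpec, params: ParameterSet, basal: StateVector,
                   L: float, grid: Optional[np.ndarray] = None,
                   protocol: Optional[Protocol] = None) -> Trajectory:
    """Step ligand to ``L`` at t = 0 and integrate over the output grid."""
    protocol = protocol or Protocol()
    if grid is None:
        grid = protocol.time_grid()
    grid = np.asarray(grid, dtype=float)
    rhs = build_rhs(spec, params)
    y0 = basal.y.copy()
    if spec.ligand_mode == "dynamic":
        y0[rhs.species["L"]] = L
    else:
        rhs.ligand = float(L)
    sol = _integrate(rhs, y0, (grid[0], grid[-1]), grid, protocol)
    prov = f"params={_params_hash(params)} L={L:.6g} t_end={grid[-1]:.6g}"
    return Trajectory(t=sol.t, y=sol.y.T, species=rhs.species, ligand=float(L),
                      provenance=prov)


def _refine_extremum(t: np.ndarray, x: np.ndarray, i: int) -> Tuple[float, float]:
    """Quadratic refinement of a grid extremum at interior index i."""
    if i == 0 or i == len(t) - 1:
        return float(t[i]), float(x[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    if denom == 0:
        return float(t1), float(x1)
    a = (t2 * (x1 - x0) + t1 * (x0 - x2) + t0 * (x2 - x1)) / denom
    b = (t2**2 * (x0 - x1) + t1**2 * (x2 - x0) + t0**2 * (x1 - x0 + x0 - x2)) / denom
    # fall back to the grid point if the parabola is degenerate or the vertex
    # escapes the bracketing interval
    if a == 0:
        return float(t1), float(x1)
    tv = -b / (2 * a)
    if not (t0 <= tv <= t2):
        return float(t1), float(x1)
    xv = a * tv**2 + b * tv + (x1 - a * t1**2 - b * t1)
    return float(tv), float(xv)


def extract_features(traj: Trajectory, pathway: int,
                     monotone_rel_tol: float = 1e-6) -> TimecourseFeatures:
    """Peak / trough / plateau summary of one pathway's alphaGTP trace.

    Basal is the value at t = 0 (the pre-ligand steady state); plateau is the
    endpoint value.  Extrema are located on the output grid and refined by a
    local quadratic fit; ties resolve to the earliest time.  A trace whose
    interior never departs from the basal-endpoint envelope by more than
    ``monotone_rel_tol`` of its span is flagged monotone, with peak = endpoint.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    t, x = traj.t, traj.alpha_gtp(pathway)
    basal = float(x[0])
    plateau = float(x[-1])
    scale = max(abs(basal), abs(plateau), float(np.max(np.abs(x))), 1e-300)
    lo, hi = min(basal, plateau), max(basal, plateau)
    overshoot = float(np.max(x)) - hi
    undershoot = lo - float(np.min(x))
    monotone = (overshoot <= monotone_rel_tol * scale
                and undershoot <= monotone_rel_tol * scale)
    if monotone:
        return TimecourseFeatures(basal=basal, peak=plateau, peak_time=float(t[-1]),
                                  trough=min(basal, plateau), trough_time=float(t[0]),
                                  plateau=plateau, monotone=True)
    i_max = int(np.argmax(x))
    i_min = int(np.argmin(x))
    pk_t, pk = _refine_extremum(t, x, i_max)
    tr_t, tr = _refine_extremum(t, x, i_min)
    return TimecourseFeatures(basal=basal, peak=pk, peak_time=pk_t,
                              trough=tr, trough_time=tr_t,
                              plateau=plateau, monotone=False)


_FEATURES = ("peak", "plateau", "trough", "peak_time", "trough_time", "basal")


def concentration_response(spec: ModelSpec, params: ParameterSet,
                           L_grid: Sequence[float], feature: str = "plateau",
                           protocol: Optional[Protocol] = None,
                           basal: Optional[StateVector] = None,
                           ) -> Dict[int, CRCurve]:
    """Feature-vs-concentration curves, one per pathway.

    One pre-equilibration is shared across the whole ligand grid (the basal
    state is ligand-independent), then one time course is run per
    concentration.
    """
    if feature not in _FEATURES:
        raise ValueError(f"unknown feature {feature!r}; choose from {_FEATURES}")
    protocol = protocol or Protocol()
    L_grid = np.asarray(L_grid, dtype=float)
    if basal is None:
        basal = pre_equilibrate(spec, params, protocol)
    out: Dict[int, List[float]] = {t + 1: [] for t in range(spec.n_gprot)}
    for L in L_grid:
        traj = run_timecourse(spec, params, basal, L, protocol=protocol)
        for th in range(1, spec.n_gprot + 1):
            out[th].append(getattr(extract_features(traj, th), feature))
    return {th: CRCurve(concentrations=L_grid, response=np.array(v),
                        feature=feature, pathway=th)
            for th, v in out.items()}


def response_surface(spec: ModelSpec, params: ParameterSet,
                     axis1: Tuple[str, Sequence[float]],
                     axis2: Tuple[str, Sequence[float]],
                     feature: str = "plateau", pathway: int = 1,
                     L: Optional[float] = None,
                     protocol: Optional[Protocol] = None) -> np.ndarray:
    """Grid evaluation of a time-course feature over two parameter axes.

    ``axis`` entries are (parameter-name, values) with names as accepted by
    :func:`gpcrbias.model_core.set_param` (e.g. ``"zeta_plus[1]"``).  Ligand
    concentration is ``L`` (defaults to ``params.L_conc``).  Pre-equilibrations
    are cached whenever the varied parameters are ligand-only (they do not
    alter the basal state).
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    protocol = protocol or Protocol()
    if L is None:
        L = params.L_conc
    # validate names early
    for nm in (name1, name2):
        get_param(params, nm)

    def ligand_only(name: str) -> bool:
        return name.partition("[")[0] in LIGAND_PARAM_NAMES

    shared_basal = None
    if ligand_only(name1) and ligand_only(name2):
        shared_basal = pre_equilibrate(spec, params, protocol)
    surf = np.empty((len(vals1), len(vals2)))
    for i, v1 in enumerate(vals1):
        for k, v2 in enumerate(vals2):
            p = params.copy()
            set_param(p, name1, v1)
            set_param(p, name2, v2)
            basal = shared_basal if shared_basal is not None else pre_equilibrate(spec, p, protocol)
            traj = run_timecourse(spec, p, basal, L, protocol=protocol)
            surf[i, k] = getattr(extract_features(traj, pathway), feature)
    return surf


def estimate_ec50(cr: CRCurve) -> Tuple[float, bool]:
    """Half-maximal concentration of a CR curve.

    For a monotone (non-decreasing, up to 1% of span) curve, returns the
    log-interpolated concentration at half of (max - min) and flag False.
    Non-monotonic curves report the location of the curve maximum instead,
    with flag True.
    """
    x, r = cr.concentrations, cr.response
    span = float(np.max(r) - np.min(r))
    if span == 0:
        return float("nan"), False
    nonmono = np.max(r) - r[-1] > 0.01 * span or np.any(np.diff(r) < -0.01 * span)
    if nonmono:
        return float(x[int(np.argmax(r))]), True
    half = np.min(r) + 0.5 * span
    i = int(np.searchsorted(r, half))
    i = min(max(i, 1), len(r) - 1)
    lx0, lx1 = np.log10(x[i - 1]), np.log10(x[i])
    r0, r1 = r[i - 1], r[i]
    frac = 0.0 if r1 == r0 else (half - r0) / (r1 - r0)
    return float(10 ** (lx0 + frac * (lx1 - lx0))), False
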