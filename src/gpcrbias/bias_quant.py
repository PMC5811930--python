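"""Quantifying pathway bias.

The operational model of agonism summarises a hyperbolic concentration-
response curve by an affinity K_D and an operational efficacy tau::

    E([A]) = basal + (Emax - basal) * tau * [A] / (K_D + (tau + 1) * [A])

(the basal term accommodates constitutive activity; setting basal = 0
recovers the classical form).  The transduction coefficient
T = log10(tau / K_D) condenses efficacy and affinity into one number per
ligand per pathway, and the relative bias factor of ligand A versus a
reference B for pathway 1 over pathway 2 is the double difference

    log10 bias = (T_A^1 - T_B^1) - (T_A^2 - T_B^2).

A mechanistic alternative that bypasses curve fitting scores each ligand by
its association constant times the pathway-1-over-pathway-2 cooperativity
ratio, normalised to the reference ligand's same quantity
(``alt_bias``).  ``dynamic_bias`` tracks bias through time by fitting the
operational model to the instantaneous concentration-response curve at each
time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import lmfit

from .model_core import ModelSpec, ParameterSet
from .simulation import CRCurve, Protocol, pre_equilibrate, run_timecourse

__all__ = [
    "OperationalFit", "BiasFactor", "UnfittableCurveError",
    "operational_response", "fit_operational", "fit_operational_bank",
    "transduction_coefficient", "bias_factor", "alt_bias", "dynamic_bias",
]


class UnfittableCurveError(ValueError):
    """Raised for near-flat curves carrying no efficacy information."""


@dataclass
class OperationalFit:
    """Fitted operational-model parameters with diagnostics."""

    Emax: float
    basal: float
    K_D: float
    tau: float
    sse: float
    success: bool
    message: str = ""
    include_basal: bool = True

    @property
    def log10_KD(self) -> float:
        return float(np.log10(self.K_D))

    @property
    def log10_tau(self) -> float:
        return float(np.log10(self.tau))


@dataclass
class BiasFactor:
    """DeltaDeltalog10(tau/K_D) bias of a ligand versus a reference."""

    log10_bias: float
    ligand: str
    reference: str
    pathways: Tuple[int, int] = (1, 2)
    time: Optional[float] = None

    @property
    def bias(self) -> float:
        return float(10.0 ** self.log10_bias)


def operational_response(A: np.ndarray, Emax: float, K_D: float, tau: float,
                         basal: float = 0.0) -> np.ndarray:
    """Operational-model response at concentrations ``A`` (M)."""
    A = np.asarray(A, dtype=float)
    return basal + (Emax - basal) * tau * A / (K_D + (tau + 1.0) * A)


# fitting bounds in log10 space: K_D within pM..mM, tau spanning the
# inverse-agonist-to-full-agonist range
_LOG_KD_BOUNDS = (-12.0, -3.0)
_LOG_TAU_BOUNDS = (-4.0, 6.0)


def _fit_once(conc, resp, log_kd0, log_tau0, emax0, basal0, include_basal,
              fixed_emax=None):
    p = lmfit.Parameters()
    p.add("log_kd", value=log_kd0, min=_LOG_KD_BOUNDS[0], max=_LOG_KD_BOUNDS[1])
    p.add("log_tau", value=log_tau0, min=_LOG_TAU_BOUNDS[0], max=_LOG_TAU_BOUNDS[1])
    if fixed_emax is None:
        p.add("Emax", value=emax0, min=0.0)
    else:
        p.add("Emax", value=float(fixed_emax), vary=False)
    if include_basal:
        p.add("basal", value=max(basal0, 0.0), min=0.0)

    def resid(pars):
        b = pars["basal"].value if include_basal else 0.0
        model = operational_response(conc, pars["Emax"].value,
                                     10.0 ** pars["log_kd"].value,
                                     10.0 ** pars["log_tau"].value, b)
        return model - resp

    with warnings.catch_warnings():
        # the tau-Emax ridge gives a singular covariance; its stderr is unused
        warnings.simplefilter("ignore", RuntimeWarning)
        return lmfit.minimize(resid, p, method="least_squares", calc_covar=False)


def fit_operational(cr: CRCurve, include_basal: bool = True,
                    emax: Optional[float] = None) -> OperationalFit:
    """Least-squares fit of the operational model to a CR curve.

    Fitting is done in log10(K_D), log10(tau) space for conditioning, with a
    multi-start initialisation read off the curve geometry: basal from the
    lowest-concentration response, Emax from the top of the curve, K_D from
    the half-rise concentration, plus coarse tau alternatives.  Raises
    :class:`UnfittableCurveError` if the response range is below 1% of the
    basal level (a flat curve pins none of the efficacy parameters).

    For a single hyperbolic curve with a freely fitted Emax, tau and Emax
    trade off along a ridge and only composite quantities (curve top,
    half-maximal concentration) are pinned.  Pass ``emax`` to fix the system
    maximal response — shared across a ligand bank per pathway, as in
    standard transduction-coefficient workflows — which makes tau
    identifiable from the degree of partial agonism (see
    :func:`fit_operational_bank`).
    """
    conc = np.asarray(cr.concentrations, dtype=float)
    resp = np.asarray(cr.response, dtype=float)
    if len(conc) < 4:
        raise ValueError("need at least 4 concentrations spanning the transition")
    basal0 = float(resp[0])
    top = float(np.max(resp))
    span = float(np.max(resp) - np.min(resp))
    if span < 0.01 * max(abs(basal0), 1e-300):
        raise UnfittableCurveError(
            f"response range {span:.3g} is below 1% of basal {basal0:.3g}; "
            "curve carries no usable efficacy information")
    # half-rise concentration as K_D guess
    half = np.min(resp) + 0.5 * span
    i = int(np.clip(np.searchsorted(resp, half), 1, len(conc) - 1)) \
        if np.all(np.diff(resp) >= 0) else int(np.argmin(np.abs(resp - half)))
    log_kd0 = float(np.clip(np.log10(conc[max(i, 1)]), *_LOG_KD_BOUNDS))
    scale = max(span, abs(top), 1e-300)
    # optimise on O(1) responses: Emax/basal simply rescale, tau and K_D do not
    resp_s = resp / scale
    basal_s, top_s = basal0 / scale, top / scale
    emax_s = None if emax is None else emax / scale

    best = None
    for log_tau0 in (-1.0, 0.0, 1.0, 2.5):
        # with tau large the apparent EC50 is K_D/tau; try shifted K_D too
        for shift in (0.0, log_tau0):
            kd0 = float(np.clip(log_kd0 + shift, *_LOG_KD_BOUNDS))
            try:
                res = _fit_once(conc, resp_s, kd0, log_tau0,
                                top_s if top_s > 0 else 1.0,
                                basal_s, include_basal, fixed_emax=emax_s)
            except Exception:   # singular starts occasionally blow up
                continue
            sse = float(np.sum(res.residual**2))
            if best is None or sse < best[0]:
                best = (sse, res)
    if best is None:
        return OperationalFit(Emax=np.nan, basal=np.nan, K_D=np.nan, tau=np.nan,
                              sse=np.inf, success=False,
                              message="all starts failed", include_basal=include_basal)
    sse, res = best
    pv = res.params.valuesdict()
    basal_fit = pv.get("basal", 0.0) * scale
    return OperationalFit(
        Emax=float(pv["Emax"]) * scale, basal=float(basal_fit),
        K_D=float(10.0 ** pv["log_kd"]), tau=float(10.0 ** pv["log_tau"]),
        sse=sse * scale**2, success=bool(res.success), message=str(res.message),
        include_basal=include_basal)


def fit_operational_bank(curves: Mapping[Tuple[str, int], CRCurve],
                         include_basal: bool = True,
                         emax_headroom: float = 1.05,
                         ) -> Dict[Tuple[str, int], OperationalFit]:
    """Fit a ligand bank with a shared per-pathway system maximum.

    For each pathway, the operational Emax is fixed at ``emax_headroom``
    times the largest response observed across the bank (the system maximal
    response, defined by the strongest agonist), and every ligand's curve is
    fitted for (K_D, tau, basal) against that common ceiling.  This makes
    tau comparable across ligands, which per-curve free-Emax fits do not
    guarantee.
    """
    pathways = sorted({pw for (_, pw) in curves})
    emax = {pw: emax_headroom * max(float(np.max(cr.response))
                                    for (lig, p), cr in curves.items() if p == pw)
            for pw in pathways}
    return {key: fit_operational(cr, include_basal=include_basal,
                                 emax=emax[key[1]])
            for key, cr in curves.items()}


def transduction_coefficient(fit: OperationalFit) -> float:
    """T = log10(tau) - log10(K_D) for a valid fit."""
    if not fit.success or not np.isfinite(fit.K_D) or not np.isfinite(fit.tau):
        raise ValueError("cannot compute a transduction coefficient from a failed fit")
    return float(np.log10(fit.tau) - np.log10(fit.K_D))


def bias_factor(fits: Mapping[Tuple[str, int], OperationalFit], ligand: str,
                reference: str, pathways: Tuple[int, int] = (1, 2)) -> BiasFactor:
    """Relative bias of ``ligand`` versus ``reference`` for pathway 1 over 2.

    ``fits`` maps (ligand-label, pathway) to operational fits; all four cells
    must be present and valid.
    """
    p1, p2 = pathways
    T: Dict[Tuple[str, int], float] = {}
    for lig in (ligand, reference):
        for pw in (p1, p2):
            if (lig, pw) not in fits:
                raise KeyError(f"missing operational fit for ligand {lig!r}, pathway {pw}")
            T[(lig, pw)] = transduction_coefficient(fits[(lig, pw)])
    log_b = (T[(ligand, p1)] - T[(reference, p1)]) - (T[(ligand, p2)] - T[(reference, p2)])
    return BiasFactor(log10_bias=float(log_b), ligand=ligand, reference=reference,
                      pathways=pathways)


def alt_bias(params_A: ParameterSet, params_ref: ParameterSet,
             pathways: Tuple[int, int] = (1, 2)) -> float:
    """Mechanistic bias score from ligand parameters alone.

    Each ligand is scored by (kL+/kL-) * (nu^1 zeta^1) / (nu^2 zeta^2), the
    association constant times the pathway-1-over-pathway-2 product of its
    coupling and activation cooperativities (equilibrium ratios
    nu = nu+/nu-, zeta = zeta+/zeta-); the bias is that score normalised by
    the reference ligand's score.
    """
    p1, p2 = pathways

    def score(p: ParameterSet) -> float:
        j1, j2, t1, t2 = p1 - 1, p2 - 1, p1 - 1, p2 - 1
        nu = (p.nu_plus / p.nu_minus)
        ze = (p.zeta_plus / p.zeta_minus)
        denom = p.kL_minus * nu[t2] * ze[j2]
        if denom == 0:
            raise ZeroDivisionError("zero denominator in alt-bias score")
        return (p.kL_plus * nu[t1] * ze[j1]) / denom

    ref = score(params_ref)
    if ref == 0:
        raise ZeroDivisionError("reference ligand has zero alt-bias score")
    return float(score(params_A) / ref)


def dynamic_bias(spec: ModelSpec, bank: Mapping[str, ParameterSet], reference: str,
                 L_grid: Sequence[float], t_grid: Sequence[float],
                 protocol: Optional[Protocol] = None,
                 pathways: Tuple[int, int] = (1, 2),
                 ) -> Dict[str, List[Optional[BiasFactor]]]:
    """Bias-factor time series for a ligand bank.

    For every ligand one time course per grid concentration is simulated
    (dense output on ``t_grid``); at each time point the instantaneous
    alphaGTP-vs-concentration curve of each pathway is fitted to the
    operational model with a bank-shared per-pathway maximum
    (:func:`fit_operational_bank`), and the bias versus ``reference``
    computed.  Fit
    failures at individual time points yield ``None`` entries for that time
    (for all ligands if the reference itself fails there).
    """
    if reference not in bank:
        raise KeyError(f"reference ligand {reference!r} not in bank")
    protocol = protocol or Protocol()
    t_grid = np.asarray(t_grid, dtype=float)
    L_grid = np.asarray(L_grid, dtype=float)
    sim_grid = np.unique(np.concatenate([[0.0], t_grid]))

    # responses[lig][pathway] has shape (n_t, n_L)
    responses: Dict[str, Dict[int, np.ndarray]] = {}
    for lig, params in bank.items():
        basal = pre_equilibrate(spec, params, protocol)
        resp = {pw: np.empty((len(sim_grid), len(L_grid))) for pw in pathways}
        for k, L in enumerate(L_grid):
            traj = run_timecourse(spec, params, basal, L, grid=sim_grid,
                                  protocol=protocol)
            for pw in pathways:
                resp[pw][:, k] = traj.alpha_gtp(pw)
        responses[lig] = resp
    t_idx = [int(np.argmin(np.abs(sim_grid - t))) for t in t_grid]

    out: Dict[str, List[Optional[BiasFactor]]] = {lig: [] for lig in bank}
    for ti, it in enumerate(t_idx):
        curves: Dict[Tuple[str, int], CRCurve] = {}
        for lig in bank:
            for pw in pathways:
                curves[(lig, pw)] = CRCurve(
                    concentrations=L_grid, response=responses[lig][pw][it],
                    feature="instantaneous", pathway=pw)
        try:
            fits = fit_operational_bank(curves)
        except (UnfittableCurveError, ValueError):
            fits = {}
        ref_ok = all(fits.get((reference, pw)) is not None
                     and fits[(reference, pw)].success for pw in pathways)
        for lig in bank:
            ok = ref_ok and all(fits.get((lig, pw)) is not None
                                and fits[(lig, pw)].success for pw in pathways)
            if not ok:
                out[lig].append(None)
                continue
            bf = bias_factor(fits, lig, reference, pathways)
            bf.time = float(t_grid[ti])
            out[lig].append(bf)
    return out
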