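"""Protocols, feature extraction, and the characteristic response regimes."""

import numpy as np
import pytest

from gpcrbias import (
    Protocol, build_rhs, concentration_response, extract_features,
    pre_equilibrate, response_surface, run_timecourse,
)
from gpcrbias.simulation import CRCurve, Trajectory, estimate_ec50
from gpcrbias.model_core import SpeciesIndex
from gpcrbias.scenarios import (
    TWO_PATHWAY, agonist_antagonist, agonist_inverse_agonist, dual_agonist,
    high_constitutive_dual_agonist, isolated_pathway, nonmonotonic_cr,
)

L_SET = (1e-7, 1e-6, 1e-5)


# ---------------------------------------------------------------------------
# pre-equilibration

def test_basal_state_is_steady(spec22, params22):
    basal = pre_equilibrate(spec22, params22)
    rhs = build_rhs(spec22, params22)
    rhs.ligand = 0.0
    assert np.max(np.abs(rhs(0.0, basal.y))) < 1e-22
    # continuing ligand-free for 1e4 s stays at basal
    traj = run_timecourse(spec22, params22, basal, 0.0,
                          grid=np.linspace(0, 1e4, 50))
    rel = np.abs(traj.y[-1] - basal.y) / np.maximum(np.abs(basal.y), 1e-30)
    active = basal.y > 1e-20 * basal.y.max()
    assert np.max(rel[active]) < 1e-9


def test_no_activation_means_no_basal_signal(spec22, params22):
    p = params22.copy()
    p.kact_plus[:] = 0.0
    p.khyd_minus[:] = 0.0     # remove the thermal reverse-hydrolysis leak
    basal = pre_equilibrate(spec22, p)
    assert basal["aGTP1"] == pytest.approx(0.0, abs=1e-25)
    assert basal["aGTP2"] == pytest.approx(0.0, abs=1e-25)


def test_constitutive_activity_trades_basal_signal(spec22, params22):
    """Raising pathway-2 constitutive activation lifts basal alphaGTP2 at the
    expense of basal alphaGTP1 (strongly-constitutive regime)."""
    p_lo = params22.copy()
    p_lo.kact_minus[1] = 1.0
    p_hi = params22.copy()
    p_hi.kact_minus[1] = 0.1
    b_lo = pre_equilibrate(spec22, p_lo)
    b_hi = pre_equilibrate(spec22, p_hi)
    assert b_hi["aGTP2"] > b_lo["aGTP2"]
    assert b_hi["aGTP1"] < b_lo["aGTP1"]


# ---------------------------------------------------------------------------
# time courses and features

def test_zero_ligand_timecourse_constant(spec22, params22):
    basal = pre_equilibrate(spec22, params22)
    traj = run_timecourse(spec22, params22, basal, 0.0)
    for pw in (1, 2):
        a = traj.alpha_gtp(pw)
        assert np.max(np.abs(a - a[0])) < 1e-6 * a[0]
        ft = extract_features(traj, pw)
        assert ft.monotone
        assert ft.basal == pytest.approx(ft.plateau, rel=1e-6)


def test_constant_trace_features():
    spec = TWO_PATHWAY
    sx = SpeciesIndex(spec)
    t = np.linspace(0, 100, 11)
    y = np.zeros((11, spec.n_species))
    y[:, sx["aGTP1"]] = 2e-10
    traj = Trajectory(t=t, y=y, species=sx)
    ft = extract_features(traj, 1)
    assert ft.monotone
    assert ft.basal == ft.peak == ft.trough == ft.plateau == 2e-10
    assert ft.trough_time == t[0]


def test_peak_time_decreases_with_concentration(spec22):
    """Dual agonist: peak-plateau transients with peak time strictly
    decreasing as ligand concentration increases."""
    p = dual_agonist()
    basal = pre_equilibrate(spec22, p)
    peak_times = []
    for L in L_SET:
        ft = extract_features(run_timecourse(spec22, p, basal, L), 1)
        assert not ft.monotone
        assert ft.peak > ft.plateau > ft.basal
        peak_times.append(ft.peak_time)
    assert np.all(np.diff(peak_times) < 0)


def test_isolated_pathway_neutral_antagonist(spec22):
    """With pathway 1 disabled and a neutral ligand, alphaGTP2 is untouched
    by ligand addition (true antagonism)."""
    p = isolated_pathway()
    basal = pre_equilibrate(spec22, p)
    traj = run_timecourse(spec22, p, basal, 1e-5)
    a2 = traj.alpha_gtp(2)
    assert np.max(np.abs(a2 - a2[0])) < 1e-9 * a2[0]


def test_apparent_inverse_agonism_of_neutral_ligand(spec22):
    """In the intact system, a pathway-1 agonist that is neutral for
    pathway 2 still depresses alphaGTP2 below basal (receptor-pool
    competition)."""
    p = agonist_antagonist()
    basal = pre_equilibrate(spec22, p)
    ft = extract_features(run_timecourse(spec22, p, basal, 1e-5), 2)
    assert ft.plateau < 0.99 * ft.basal


def test_inverse_agonist_undershoot_and_trough_timing(spec22):
    """Pathway-2 inverse agonist: alphaGTP2 undershoots below both basal and
    its final level, and the trough time grows with concentration."""
    p = agonist_inverse_agonist()
    basal = pre_equilibrate(spec22, p)
    trough_times = []
    for L in L_SET:
        ft = extract_features(run_timecourse(spec22, p, basal, L), 2)
        assert ft.trough < 0.999 * min(ft.basal, ft.plateau)
        trough_times.append(ft.trough_time)
    assert np.all(np.diff(trough_times) > 0)


def test_dynamic_interconversion(spec22):
    """Balanced dual agonist with strongly constitutive pathway 2: the
    alphaGTP1 response rises above basal early but settles below basal at
    long times (agonist-to-apparent-inverse-agonist inter-conversion)."""
    p = high_constitutive_dual_agonist()
    basal = pre_equilibrate(spec22, p)
    traj = run_timecourse(spec22, p, basal, 1e-5,
                          grid=np.geomspace(1, 3e4, 120))
    a1 = traj.alpha_gtp(1)
    b = basal["aGTP1"]
    assert a1.max() > 1.02 * b
    assert a1[-1] < 0.98 * b


def test_peak_refinement_grid_stability(spec22):
    """Doubling the output grid changes the refined peak value by < 0.1%."""
    p = dual_agonist()
    basal = pre_equilibrate(spec22, p)
    f1 = extract_features(run_timecourse(
        spec22, p, basal, 1e-6, grid=np.linspace(0, 1200, 400)), 1)
    f2 = extract_features(run_timecourse(
        spec22, p, basal, 1e-6, grid=np.linspace(0, 1200, 800)), 1)
    assert f2.peak == pytest.approx(f1.peak, rel=1e-3)


# ---------------------------------------------------------------------------
# concentration-response

def test_neutral_ligand_flat_cr(spec22, params22):
    curves = concentration_response(spec22, params22,
                                    np.geomspace(1e-10, 1e-4, 6))
    for cr in curves.values():
        span = cr.response.max() - cr.response.min()
        assert span < 1e-9 * cr.response[0]


def test_nonmonotonic_plateau_cr(spec22):
    """High pathway-2 constitutive activity makes the pathway-1 plateau CR
    curve non-monotonic, and the flagged half-max estimate reports the
    location of the interior maximum."""
    p = nonmonotonic_cr()
    curves = concentration_response(spec22, p, np.geomspace(1e-10, 1e-4, 10))
    r = curves[1].response
    i_max = int(np.argmax(r))
    assert 0 < i_max < len(r) - 1
    assert r[i_max] > 1.02 * r[-1]
    ec50, flagged = estimate_ec50(curves[1])
    assert flagged
    assert ec50 == pytest.approx(curves[1].concentrations[i_max])


def test_receptor_number_shifts_cr(spec22):
    """Lower receptor expression depresses peak and plateau maxima and
    shifts the plateau EC50 rightward (loss of receptor reserve).  The peak
    feature's potency is binding-limited in this regime and barely moves, so
    the EC50 check applies to the plateau."""
    Ls = np.geomspace(1e-10, 1e-4, 19)
    out = {}
    for R_tot in (4.15e-11, 4.15e-9):
        p = dual_agonist(1000.0, 100.0)
        p.R_tot = R_tot
        out[R_tot] = {feat: concentration_response(spec22, p, Ls, feat)[1]
                      for feat in ("peak", "plateau")}
    for feat in ("peak", "plateau"):
        lo, hi = out[4.15e-11][feat], out[4.15e-9][feat]
        assert lo.response.max() < hi.response.max()
    ec_lo, fl_lo = estimate_ec50(out[4.15e-11]["plateau"])
    ec_hi, fl_hi = estimate_ec50(out[4.15e-9]["plateau"])
    assert not fl_lo and not fl_hi
    assert ec_lo > ec_hi


def test_crcurve_validation():
    with pytest.raises(ValueError):
        CRCurve(concentrations=np.array([1e-9, 1e-8]), response=np.array([1.0]))
    with pytest.raises(ValueError):
        CRCurve(concentrations=np.array([1e-8, 1e-9]),
                response=np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# response surfaces

def test_degenerate_surface_equals_direct_feature(spec22):
    p = dual_agonist(100.0, 100.0)
    surf = response_surface(spec22, p, ("zeta_plus[1]", [100.0]),
                            ("zeta_plus[2]", [100.0]), feature="plateau",
                            pathway=1, L=1e-6)
    assert surf.shape == (1, 1)
    basal = pre_equilibrate(spec22, p)
    direct = extract_features(run_timecourse(spec22, p, basal, 1e-6), 1).plateau
    assert surf[0, 0] == pytest.approx(direct, rel=1e-8)


def test_efficacy_surface_reciprocal_trend(spec22):
    """Across the agonist range, raising zeta+1 raises pathway-1 peak and
    plateau while lowering pathway 2's."""
    p = dual_agonist(100.0, 100.0)
    z1 = [100.0, 1000.0]
    for feat in ("peak", "plateau"):
        s1 = response_surface(spec22, p, ("zeta_plus[1]", z1),
                              ("zeta_plus[2]", [100.0]), feature=feat,
                              pathway=1, L=1e-5).ravel()
        s2 = response_surface(spec22, p, ("zeta_plus[1]", z1),
                              ("zeta_plus[2]", [100.0]), feature=feat,
                              pathway=2, L=1e-5).ravel()
        assert s1[1] > s1[0]
        assert s2[1] < s2[0]


def test_nonsignalling_cross_state_sequesters_g_protein(spec22):
    """Opening a non-signalling cross state (mu+12 > 0 with kGTP+12 = 0)
    lowers the pathway-2 peak response: G2 is sequestered in R*1-G2
    complexes that never exchange nucleotide."""
    p = dual_agonist(100.0, 100.0)
    surf = response_surface(spec22, p, ("mu_plus[1,2]", [0.0, 1.0]),
                            ("zeta_plus[2]", [100.0]), feature="peak",
                            pathway=2, L=1e-5).ravel()
    assert surf[1] < surf[0]


def test_surface_unknown_parameter(spec22, params22):
    with pytest.raises(KeyError):
        response_surface(spec22, params22, ("zeta_plus[1]", [1.0]),
                         ("not_a_rate", [1.0]))


def test_protocol_validation():
    with pytest.raises(ValueError):
        Protocol(post_ligand_time=-1.0)
    with pytest.raises(ValueError):
        Protocol(grid="cubic")
    g = Protocol(grid="log", n_points=50, t_min=1e-3).time_grid()
    assert g[0] == 0.0 and len(g) == 50 and np.all(np.diff(g) > 0)
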