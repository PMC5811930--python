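"""Independent oracles for the mass-action right-hand side.

``literal_rhs`` is a direct, loop-based transcription of the governing
ODE system for the general N*, NG scheme — written against the printed
per-species balance equations, independently of the package's
reaction-network construction.  ``single_cube_rhs`` is a separately
hand-coded RHS for the minimal one-active-state, one-G-protein cubic
ternary complex with G cycle (constant ligand), with every term written
out explicitly.
"""

from __future__ import annotations

import numpy as np

from gpcrbias.model_core import ModelSpec, ParameterSet, SpeciesIndex


def literal_rhs(spec: ModelSpec, params: ParameterSet, y: np.ndarray,
                ligand: float | None = None) -> np.ndarray:
    """Term-by-term evaluation of the per-species balance equations."""
    sx = SpeciesIndex(spec)
    ns, ng = spec.n_active, spec.n_gprot
    p = params
    dyn = spec.ligand_mode == "dynamic"
    L = y[sx["L"]] if dyn else (params.L_conc if ligand is None else ligand)

    def g(name):
        return y[sx[name]]

    dy = np.zeros_like(y)

    R, LR = g("R"), g("LR")
    Rs = [g(f"R*{j+1}") for j in range(ns)]
    LRs = [g(f"LR*{j+1}") for j in range(ns)]
    G = [g(f"G{t+1}") for t in range(ng)]
    RG = [g(f"RG{t+1}") for t in range(ng)]
    LRG = [g(f"LRG{t+1}") for t in range(ng)]
    RsG = [[g(f"R*{j+1}G{t+1}") for t in range(ng)] for j in range(ns)]
    LRsG = [[g(f"LR*{j+1}G{t+1}") for t in range(ng)] for j in range(ns)]
    aGTP = [g(f"aGTP{t+1}") for t in range(ng)]
    aGDP = [g(f"aGDP{t+1}") for t in range(ng)]
    bg = [g(f"bg{t+1}") for t in range(ng)]

    kLp, kLm = p.kL_plus, p.kL_minus
    kap, kam = p.kact_plus, p.kact_minus
    kGp, kGm = p.kG_plus, p.kG_minus
    mup, mum = p.mu_plus, p.mu_minus
    nup, num = p.nu_plus, p.nu_minus
    zp, zm = p.zeta_plus, p.zeta_minus
    kx = p.kGTP_plus
    khp, khm = p.khyd_plus, p.khyd_minus
    krp, krm = p.kGRA_plus, p.kGRA_minus

    # d[R]/dt
    dy[sx["R"]] = (kLm * LR - kLp * L * R
                   + sum(kam[j] * Rs[j] - kap[j] * R for j in range(ns))
                   + sum(kGm[t] * RG[t] - kGp[t] * R * G[t] for t in range(ng)))
    # d[L]/dt (dynamic mode only)
    if dyn:
        dy[sx["L"]] = (kLm * LR - kLp * L * R
                       + sum(zm[j] * kLm * LRs[j] - zp[j] * kLp * L * Rs[j]
                             for j in range(ns))
                       + sum(num[t] * kLm * LRG[t] - nup[t] * kLp * L * RG[t]
                             for t in range(ng))
                       + sum(zm[j] * num[t] * kLm * LRsG[j][t]
                             - zp[j] * nup[t] * kLp * L * RsG[j][t]
                             for t in range(ng) for j in range(ns)))
    # d[LR]/dt
    dy[sx["LR"]] = (kLp * L * R - kLm * LR
                    + sum(zm[j] * kam[j] * LRs[j] - zp[j] * kap[j] * LR
                          for j in range(ns))
                    + sum(num[t] * kGm[t] * LRG[t] - nup[t] * kGp[t] * LR * G[t]
                          for t in range(ng)))
    # d[R*j]/dt
    for j in range(ns):
        dy[sx[f"R*{j+1}"]] = (kap[j] * R - kam[j] * Rs[j]
                              + zm[j] * kLm * LRs[j] - zp[j] * kLp * L * Rs[j]
                              + sum(mum[j, t] * kGm[t] * RsG[j][t]
                                    - mup[j, t] * kGp[t] * Rs[j] * G[t]
                                    for t in range(ng))
                              + sum(kx[j, t] * RsG[j][t] for t in range(ng)))
    # d[LR*j]/dt
    for j in range(ns):
        dy[sx[f"LR*{j+1}"]] = (zp[j] * kap[j] * LR - zm[j] * kam[j] * LRs[j]
                               + zp[j] * kLp * L * Rs[j] - zm[j] * kLm * LRs[j]
                               + sum(mum[j, t] * num[t] * kGm[t] * LRsG[j][t]
                                     - mup[j, t] * nup[t] * kGp[t] * LRs[j] * G[t]
                                     for t in range(ng))
                               + sum(num[t] * kx[j, t] * LRsG[j][t]
                                     for t in range(ng)))
    # d[RG_t]/dt
    for t in range(ng):
        dy[sx[f"RG{t+1}"]] = (kGp[t] * R * G[t] - kGm[t] * RG[t]
                              + num[t] * kLm * LRG[t] - nup[t] * kLp * L * RG[t]
                              + sum(mum[j, t] * kam[j] * RsG[j][t]
                                    - mup[j, t] * kap[j] * RG[t]
                                    for j in range(ns)))
    # d[LRG_t]/dt
    for t in range(ng):
        dy[sx[f"LRG{t+1}"]] = (nup[t] * kGp[t] * LR * G[t] - num[t] * kGm[t] * LRG[t]
                               + nup[t] * kLp * L * RG[t] - num[t] * kLm * LRG[t]
                               + sum(mum[j, t] * zm[j] * kam[j] * LRsG[j][t]
                                     - mup[j, t] * zp[j] * kap[j] * LRG[t]
                                     for j in range(ns)))
    # d[R*jG_t]/dt
    for j in range(ns):
        for t in range(ng):
            dy[sx[f"R*{j+1}G{t+1}"]] = (
                mup[j, t] * kGp[t] * Rs[j] * G[t] - mum[j, t] * kGm[t] * RsG[j][t]
                + zm[j] * num[t] * kLm * LRsG[j][t]
                - zp[j] * nup[t] * kLp * L * RsG[j][t]
                + mup[j, t] * kap[j] * RG[t] - mum[j, t] * kam[j] * RsG[j][t]
                - kx[j, t] * RsG[j][t])
    # d[LR*jG_t]/dt
    for j in range(ns):
        for t in range(ng):
            dy[sx[f"LR*{j+1}G{t+1}"]] = (
                mup[j, t] * nup[t] * kGp[t] * LRs[j] * G[t]
                - mum[j, t] * num[t] * kGm[t] * LRsG[j][t]
                + zp[j] * nup[t] * kLp * L * RsG[j][t]
                - zm[j] * num[t] * kLm * LRsG[j][t]
                + mup[j, t] * zp[j] * kap[j] * LRG[t]
                - mum[j, t] * zm[j] * kam[j] * LRsG[j][t]
                - num[t] * kx[j, t] * LRsG[j][t])
    # d[G_t]/dt
    for t in range(ng):
        dy[sx[f"G{t+1}"]] = (kGm[t] * RG[t] - kGp[t] * R * G[t]
                             + num[t] * kGm[t] * LRG[t] - nup[t] * kGp[t] * LR * G[t]
                             + krp[t] * aGDP[t] * bg[t] - krm[t] * G[t]
                             + sum(mum[j, t] * kGm[t] * RsG[j][t]
                                   - mup[j, t] * kGp[t] * Rs[j] * G[t]
                                   for j in range(ns))
                             + sum(mum[j, t] * num[t] * kGm[t] * LRsG[j][t]
                                   - mup[j, t] * nup[t] * kGp[t] * LRs[j] * G[t]
                                   for j in range(ns)))
    # d[aGDP_t]/dt
    for t in range(ng):
        dy[sx[f"aGDP{t+1}"]] = (khp[t] * aGTP[t] - khm[t] * aGDP[t]
                                + krm[t] * G[t] - krp[t] * aGDP[t] * bg[t])
    # d[bg_t]/dt
    for t in range(ng):
        dy[sx[f"bg{t+1}"]] = (krm[t] * G[t] - krp[t] * aGDP[t] * bg[t]
                              + sum(kx[j, t] * RsG[j][t]
                                    + num[t] * kx[j, t] * LRsG[j][t]
                                    for j in range(ns)))
    # d[aGTP_t]/dt
    for t in range(ng):
        dy[sx[f"aGTP{t+1}"]] = (khm[t] * aGDP[t] - khp[t] * aGTP[t]
                                + sum(kx[j, t] * RsG[j][t]
                                      + num[t] * kx[j, t] * LRsG[j][t]
                                      for j in range(ns)))
    return dy


# species order for the hand-coded single cube (constant ligand):
# R, LR, R*, LR*, G, RG, LRG, R*G, LR*G, aGTP, aGDP, bg
def single_cube_rhs(p: ParameterSet, y: np.ndarray, L: float) -> np.ndarray:
    """Explicit 12-species single cubic ternary complex + G cycle RHS."""
    (R, LR, Rs, LRs, G, RG, LRG, RsG, LRsG, aGTP, aGDP, bg) = y
    kLp, kLm = p.kL_plus, p.kL_minus
    kap, kam = p.kact_plus[0], p.kact_minus[0]
    kGp, kGm = p.kG_plus[0], p.kG_minus[0]
    mup, mum = p.mu_plus[0, 0], p.mu_minus[0, 0]
    nup, num = p.nu_plus[0], p.nu_minus[0]
    zp, zm = p.zeta_plus[0], p.zeta_minus[0]
    kx = p.kGTP_plus[0, 0]
    khp, khm = p.khyd_plus[0], p.khyd_minus[0]
    krp, krm = p.kGRA_plus[0], p.kGRA_minus[0]

    dR = kLm * LR - kLp * L * R + kam * Rs - kap * R + kGm * RG - kGp * R * G
    dLR = (kLp * L * R - kLm * LR + zm * kam * LRs - zp * kap * LR
           + num * kGm * LRG - nup * kGp * LR * G)
    dRs = (kap * R - kam * Rs + zm * kLm * LRs - zp * kLp * L * Rs
           + mum * kGm * RsG - mup * kGp * Rs * G + kx * RsG)
    dLRs = (zp * kap * LR - zm * kam * LRs + zp * kLp * L * Rs - zm * kLm * LRs
            + mum * num * kGm * LRsG - mup * nup * kGp * LRs * G + num * kx * LRsG)
    dG = (kGm * RG - kGp * R * G + num * kGm * LRG - nup * kGp * LR * G
          + krp * aGDP * bg - krm * G + mum * kGm * RsG - mup * kGp * Rs * G
          + mum * num * kGm * LRsG - mup * nup * kGp * LRs * G)
    dRG = (kGp * R * G - kGm * RG + num * kLm * LRG - nup * kLp * L * RG
           + mum * kam * RsG - mup * kap * RG)
    dLRG = (nup * kGp * LR * G - num * kGm * LRG + nup * kLp * L * RG
            - num * kLm * LRG + mum * zm * kam * LRsG - mup * zp * kap * LRG)
    dRsG = (mup * kGp * Rs * G - mum * kGm * RsG + zm * num * kLm * LRsG
            - zp * nup * kLp * L * RsG + mup * kap * RG - mum * kam * RsG
            - kx * RsG)
    dLRsG = (mup * nup * kGp * LRs * G - mum * num * kGm * LRsG
             + zp * nup * kLp * L * RsG - zm * num * kLm * LRsG
             + mup * zp * kap * LRG - mum * zm * kam * LRsG - num * kx * LRsG)
    daGTP = khm * aGDP - khp * aGTP + kx * RsG + num * kx * LRsG
    daGDP = khp * aGTP - khm * aGDP + krm * G - krp * aGDP * bg
    dbg = krm * G - krp * aGDP * bg + kx * RsG + num * kx * LRsG
    return np.array([dR, dLR, dRs, dLRs, dG, dRG, dLRG, dRsG, dLRsG,
                     daGTP, daGDP, dbg])


def random_parameters(spec: ModelSpec, rng: np.random.Generator) -> ParameterSet:
    """Log-uniform random rate constants with positive cooperativities."""
    ns, ng = spec.n_active, spec.n_gprot
    u = lambda lo, hi, size=None: 10.0 ** rng.uniform(lo, hi, size)
    return ParameterSet(
        kL_plus=u(3, 6), kL_minus=u(-4, -1),
        kact_plus=u(-3, 0, ns), kact_minus=u(-1, 3, ns),
        kG_plus=u(4, 7, ng), kG_minus=u(-4, 0, ng),
        mu_plus=u(-2, 2, (ns, ng)), mu_minus=u(-1, 1, (ns, ng)),
        nu_plus=u(-2, 2, ng), nu_minus=u(-1, 1, ng),
        zeta_plus=u(-2, 3, ns), zeta_minus=u(-1, 1, ns),
        kGTP_plus=u(-2, 1, (ns, ng)),
        khyd_plus=u(-3, 0, ng), khyd_minus=u(-9, -6, ng),
        kGRA_plus=u(3, 7, ng), kGRA_minus=u(-5, -3, ng),
        R_tot=u(-10, -8), G_tot=u(-9, -7, ng), L_conc=u(-9, -5))


def random_state(spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    return 10.0 ** rng.uniform(-12, -8, spec.n_species)
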