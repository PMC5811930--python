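"""Species enumeration and mass-action right-hand side for the biased-signalling scheme.

The model describes a single receptor population that can occupy an inactive
conformation ``R`` or one of ``N*`` active conformations ``R*j``, bind a single
ligand ``L``, and couple any of ``NG`` G proteins ``G_theta``.  Each (j, theta)
pair forms a cubic ternary complex: the three axes of the cube are ligand
binding, receptor activation and G-protein coupling, and the cooperativity
factors ``mu`` (activation <-> coupling), ``nu`` (ligand <-> coupling) and
``zeta`` (ligand <-> activation) couple the faces.  Ternary complexes
``R*jG_theta`` / ``LR*jG_theta`` may dissociate irreversibly (GDP/GTP exchange),
feeding the G-protein cycle ``alphaGTP -> alphaGDP -> (+ betagamma) -> G``.
The per-pathway signalling readout is ``[alphaGTP_theta]``.

Units are molar and seconds throughout.

Species ordering (canonical, stable across the package)::

    R, LR,
    R*1..R*N*, LR*1..LR*N*,
    G1..GNG, RG1..RGNG, LRG1..LRGNG,
    R*jGtheta  (j outer, theta inner),
    LR*jGtheta (j outer, theta inner),
    aGTP1..aGTPNG, aGDP1..aGDPNG, bg1..bgNG,
    [L last, only in dynamic-ligand mode]
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "ModelSpec", "ParameterSet", "SpeciesIndex", "StateVector",
    "enumerate_species", "build_rhs", "conservation_totals",
    "aggregate_receptor_pools", "default_parameters", "MassActionRHS",
    "get_param", "set_param", "LIGAND_PARAM_NAMES",
]

# sentinel reactant index meaning "the ligand, held at a constant concentration"
_LIGAND_CONST = -2
_NONE = -1


@dataclass(frozen=True)
class ModelSpec:
    """Structural choice fixing the species set and ODE dimension.

    Parameters
    ----------
    n_active
        Number of active receptor conformations ``N*`` (>= 1).
    n_gprot
        Number of G proteins ``NG`` (>= 1).
    ligand_mode
        ``"constant"`` treats ``[L]`` as a held parameter (the default used
        throughout; ligand is in vast excess over receptor), ``"dynamic"``
        adds an ODE for ``[L]`` and the species ``L`` to the state.
    """

    n_active: int = 2
    n_gprot: int = 2
    ligand_mode: str = "constant"

    def __post_init__(self) -> None:
        if self.n_active < 1 or int(self.n_active) != self.n_active:
            raise ValueError(f"n_active must be a positive integer, got {self.n_active}")
        if self.n_gprot < 1 or int(self.n_gprot) != self.n_gprot:
            raise ValueError(f"n_gprot must be a positive integer, got {self.n_gprot}")
        if self.ligand_mode not in ("constant", "dynamic"):
            raise ValueError(f"ligand_mode must be 'constant' or 'dynamic', got {self.ligand_mode!r}")

    @property
    def n_species(self) -> int:
        ns, ng = self.n_active, self.n_gprot
        if self.ligand_mode == "dynamic":
            return 3 + 2 * ns + 6 * ng + 2 * ns * ng
        return 2 * (1 + ns + 3 * ng + ns * ng)


class SpeciesIndex:
    """Bidirectional species-name <-> state-position mapping for a ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        ns, ng = spec.n_active, spec.n_gprot
        names: List[str] = ["R", "LR"]
        names += [f"R*{j}" for j in range(1, ns + 1)]
        names += [f"LR*{j}" for j in range(1, ns + 1)]
        names += [f"G{t}" for t in range(1, ng + 1)]
        names += [f"RG{t}" for t in range(1, ng + 1)]
        names += [f"LRG{t}" for t in range(1, ng + 1)]
        names += [f"R*{j}G{t}" for j in range(1, ns + 1) for t in range(1, ng + 1)]
        names += [f"LR*{j}G{t}" for j in range(1, ns + 1) for t in range(1, ng + 1)]
        names += [f"aGTP{t}" for t in range(1, ng + 1)]
        names += [f"aGDP{t}" for t in range(1, ng + 1)]
        names += [f"bg{t}" for t in range(1, ng + 1)]
        if spec.ligand_mode == "dynamic":
            names.append("L")
        self.names: Tuple[str, ...] = tuple(names)
        self._pos: Dict[str, int] = {n: i for i, n in enumerate(names)}
        assert len(self.names) == spec.n_species

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> int:
        return self._pos[name]

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def name(self, i: int) -> str:
        return self.names[i]

    # -- grouped index helpers -------------------------------------------
    @property
    def receptor_indices(self) -> List[int]:
        """All receptor-containing species (2(1+N*)(1+NG) of them)."""
        out = []
        for n in self.names:
            if n == "L" or n.startswith(("G", "aGTP", "aGDP", "bg")):
                continue
            out.append(self._pos[n])
        return out

    def alpha_indices(self, theta: int) -> List[int]:
        """Species containing the alpha subunit of G protein theta (1-based)."""
        ns = self.spec.n_active
        names = [f"G{theta}", f"RG{theta}", f"LRG{theta}", f"aGTP{theta}", f"aGDP{theta}"]
        names += [f"R*{j}G{theta}" for j in range(1, ns + 1)]
        names += [f"LR*{j}G{theta}" for j in range(1, ns + 1)]
        return [self._pos[n] for n in names]

    def betagamma_indices(self, theta: int) -> List[int]:
        ns = self.spec.n_active
        names = [f"G{theta}", f"RG{theta}", f"LRG{theta}", f"bg{theta}"]
        names += [f"R*{j}G{theta}" for j in range(1, ns + 1)]
        names += [f"LR*{j}G{theta}" for j in range(1, ns + 1)]
        return [self._pos[n] for n in names]


def enumerate_species(spec: ModelSpec) -> SpeciesIndex:
    """Return the canonical species ordering for ``spec``.

    Raises ``ValueError`` for non-positive ``N*`` or ``NG`` (via ModelSpec).
    """
    return SpeciesIndex(spec)


@dataclass
class ParameterSet:
    """Kinetic rate constants, cooperativity multipliers and totals.

    ``*_plus`` / ``*_minus`` are forward/backward kinetic constants; the
    corresponding equilibrium constants are exposed as derived ratios
    (``K_L``, ``K_G``, ``K_act``).  Arrays are indexed ``[j]`` over active
    states and ``[theta]`` (or ``[j, theta]``) over G proteins, 0-based in
    code, 1-based in the naming convention of :func:`get_param`.

    Bimolecular constants are in M^-1 s^-1, unimolecular in s^-1,
    cooperativity multipliers dimensionless, totals in M.
    """

    kL_plus: float
    kL_minus: float
    kact_plus: np.ndarray      # (N*,)
    kact_minus: np.ndarray     # (N*,)
    kG_plus: np.ndarray        # (NG,)
    kG_minus: np.ndarray       # (NG,)
    mu_plus: np.ndarray        # (N*, NG)
    mu_minus: np.ndarray       # (N*, NG)
    nu_plus: np.ndarray        # (NG,)
    nu_minus: np.ndarray       # (NG,)
    zeta_plus: np.ndarray      # (N*,)
    zeta_minus: np.ndarray     # (N*,)
    kGTP_plus: np.ndarray      # (N*, NG); 0 entries = non-signalling state
    khyd_plus: np.ndarray      # (NG,)
    khyd_minus: np.ndarray     # (NG,)
    kGRA_plus: np.ndarray      # (NG,)
    kGRA_minus: np.ndarray     # (NG,)
    R_tot: float
    G_tot: np.ndarray          # (NG,)
    L_conc: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (list, tuple)) or (isinstance(v, np.ndarray)):
                setattr(self, f.name, np.asarray(v, dtype=float))

    # -- derived equilibrium constants -----------------------------------
    @property
    def K_L(self) -> float:
        """Ligand association equilibrium constant kL+/kL- (M^-1)."""
        return self.kL_plus / self.kL_minus

    @property
    def K_G(self) -> np.ndarray:
        return self.kG_plus / self.kG_minus

    @property
    def K_act(self) -> np.ndarray:
        return self.kact_plus / self.kact_minus

    def copy(self) -> "ParameterSet":
        kw = {}
        for f in fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return ParameterSet(**kw)

    def evolve(self, **updates) -> "ParameterSet":
        """Return a copy with named fields replaced."""
        out = self.copy()
        for k, v in updates.items():
            if not hasattr(out, k):
                raise AttributeError(f"unknown parameter field {k!r}")
            cur = getattr(out, k)
            setattr(out, k, np.asarray(v, dtype=float) if isinstance(cur, np.ndarray) else float(v))
        return out

    def validate(self, spec: ModelSpec) -> None:
        """Check shapes against ``spec`` and sign constraints."""
        ns, ng = spec.n_active, spec.n_gprot
        shapes = {
            "kact_plus": (ns,), "kact_minus": (ns,),
            "kG_plus": (ng,), "kG_minus": (ng,),
            "mu_plus": (ns, ng), "mu_minus": (ns, ng),
            "nu_plus": (ng,), "nu_minus": (ng,),
            "zeta_plus": (ns,), "zeta_minus": (ns,),
            "kGTP_plus": (ns, ng),
            "khyd_plus": (ng,), "khyd_minus": (ng,),
            "kGRA_plus": (ng,), "kGRA_minus": (ng,),
            "G_tot": (ng,),
        }
        for name, shp in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shp} for N*={ns}, NG={ng}")
        for name in ("kL_plus", "kL_minus", "R_tot", "L_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name, shp in shapes.items():
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative everywhere")


def default_parameters(spec: ModelSpec) -> ParameterSet:
    """Baseline parameter set: a quiescent, pathway-exclusive system.

    Stated, widely used magnitudes: kL+ = 1e5 M^-1 s^-1, kact+ = 0.05 s^-1,
    kact- = 100 s^-1 (low constitutive activity), kGTP+ = 1 s^-1 on matched
    (j = theta) pairs, khyd- = 1e-8 s^-1, kGRA- = 1.3e-4 s^-1,
    R_tot = 4.15e-9 M.  The remaining constants are set at magnitudes typical
    of kinetic G-protein-cycle models: agonist K_D = 50 nM (kL- = 5e-3 s^-1),
    receptor-G collision coupling that is slowly reversible relative to
    nucleotide exchange (kG+ = 1e5 M^-1 s^-1, kG- = 1e-3 s^-1 << kGTP+), a
    slow cycle (khyd+ = 1e-2 s^-1, reassociation kGRA+ = 1e5 M^-1 s^-1), and
    G_tot = 1e-8 M per pathway.  In this regime an agonist step produces the
    characteristic peak-plateau alphaGTP transient (burst consumption of the
    heterotrimer pool, then a lower reassociation-limited steady state), and
    receptor-pool competition between the two pathways is expressed in the
    responses rather than masked by free-G buffering.

    Cross-state default is exclusive specificity: mu[j,theta] = 1 and
    kGTP+[j,theta] = 1 for j = theta, both 0 otherwise (zero entries remove
    those reactions).  All ligand cooperativities default to 1 (a neutral
    ligand); scenario code overrides zeta/nu to make agonists.
    """
    ns, ng = spec.n_active, spec.n_gprot
    eye = np.zeros((ns, ng))
    for j in range(min(ns, ng)):
        eye[j, j] = 1.0
    return ParameterSet(
        kL_plus=1e5,
        kL_minus=5e-3,
        kact_plus=np.full(ns, 0.05),
        kact_minus=np.full(ns, 100.0),
        kG_plus=np.full(ng, 1e5),
        kG_minus=np.full(ng, 1e-3),
        mu_plus=eye.copy(),
        mu_minus=np.ones((ns, ng)),
        nu_plus=np.ones(ng),
        nu_minus=np.ones(ng),
        zeta_plus=np.ones(ns),
        zeta_minus=np.ones(ns),
        kGTP_plus=eye.copy(),
        khyd_plus=np.full(ng, 0.01),
        khyd_minus=np.full(ng, 1e-8),
        kGRA_plus=np.full(ng, 1e5),
        kGRA_minus=np.full(ng, 1.3e-4),
        R_tot=4.15e-9,
        G_tot=np.full(ng, 1e-8),
        L_conc=0.0,
    )


# ---------------------------------------------------------------------------
# parameter addressing by name, e.g. "zeta_plus[2]", "mu_plus[1,2]", "R_tot"
# (1-based indices, matching the j / theta superscripts of the scheme)

LIGAND_PARAM_NAMES = ("kL_plus", "kL_minus", "zeta_plus", "zeta_minus",
                      "nu_plus", "nu_minus", "L_conc")
"""Fields that only matter once ligand is present: they do not affect the
ligand-free basal state, so pre-equilibrations may be shared across them."""


def _parse_param_name(name: str) -> Tuple[str, Tuple[int, ...]]:
    name = name.strip()
    if "[" in name:
        base, _, rest = name.partition("[")
        idx = tuple(int(s) - 1 for s in rest.rstrip("]").split(","))
        return base, idx
    return name, ()


def get_param(params: ParameterSet, name: str) -> float:
    base, idx = _parse_param_name(name)
    if not hasattr(params, base):
        raise KeyError(f"unknown parameter {name!r}")
    v = getattr(params, base)
    return float(v[idx] if idx else v)


def set_param(params: ParameterSet, name: str, value: float) -> None:
    """Set a (possibly indexed) parameter in place."""
    base, idx = _parse_param_name(name)
    if not hasattr(params, base):
        raise KeyError(f"unknown parameter {name!r}")
    v = getattr(params, base)
    if idx:
        v[idx] = value
    else:
        setattr(params, base, float(value))


# ---------------------------------------------------------------------------
# reaction network construction

@dataclass
class _Reaction:
    k: float
    reactants: Tuple[int, ...]   # species indices; _LIGAND_CONST for held ligand
    products: Tuple[int, ...]


def _build_reactions(spec: ModelSpec, params: ParameterSet) -> List[_Reaction]:
    """Directed mass-action reactions for the full scheme.

    Reversible transitions are entered as two directed reactions; reactions
    with a zero rate constant are dropped (so mu = 0 or kGTP+ = 0 removes the
    reaction rather than contributing a zero rate).
    """
    sx = SpeciesIndex(spec)
    ns, ng = spec.n_active, spec.n_gprot
    dyn = spec.ligand_mode == "dynamic"
    L = sx["L"] if dyn else _LIGAND_CONST
    p = params
    rxns: List[_Reaction] = []

    def rev(kf, kb, reac_f, prod_f):
        if kf > 0:
            rxns.append(_Reaction(float(kf), tuple(reac_f), tuple(prod_f)))
        if kb > 0:
            rxns.append(_Reaction(float(kb), tuple(prod_f), tuple(reac_f)))

    R, LR = sx["R"], sx["LR"]
    # ligand binding / receptor activation / G coupling, per cube edge
    rev(p.kL_plus, p.kL_minus, (L, R), (LR,))
    for j in range(ns):
        Rj, LRj = sx[f"R*{j+1}"], sx[f"LR*{j+1}"]
        rev(p.kact_plus[j], p.kact_minus[j], (R,), (Rj,))
        rev(p.zeta_plus[j] * p.kL_plus, p.zeta_minus[j] * p.kL_minus, (L, Rj), (LRj,))
        rev(p.zeta_plus[j] * p.kact_plus[j], p.zeta_minus[j] * p.kact_minus[j], (LR,), (LRj,))
    for t in range(ng):
        G, RG, LRG = sx[f"G{t+1}"], sx[f"RG{t+1}"], sx[f"LRG{t+1}"]
        rev(p.kG_plus[t], p.kG_minus[t], (R, G), (RG,))
        rev(p.nu_plus[t] * p.kL_plus, p.nu_minus[t] * p.kL_minus, (L, RG), (LRG,))
        rev(p.nu_plus[t] * p.kG_plus[t], p.nu_minus[t] * p.kG_minus[t], (LR, G), (LRG,))
        for j in range(ns):
            Rj, LRj = sx[f"R*{j+1}"], sx[f"LR*{j+1}"]
            RjG, LRjG = sx[f"R*{j+1}G{t+1}"], sx[f"LR*{j+1}G{t+1}"]
            mp, mm = p.mu_plus[j, t], p.mu_minus[j, t]
            rev(mp * p.kG_plus[t], mm * p.kG_minus[t], (Rj, G), (RjG,))
            rev(mp * p.kact_plus[j], mm * p.kact_minus[j], (RG,), (RjG,))
            rev(p.zeta_plus[j] * p.nu_plus[t] * p.kL_plus,
                p.zeta_minus[j] * p.nu_minus[t] * p.kL_minus, (L, RjG), (LRjG,))
            rev(mp * p.nu_plus[t] * p.kG_plus[t], mm * p.nu_minus[t] * p.kG_minus[t],
                (LRj, G), (LRjG,))
            rev(mp * p.zeta_plus[j] * p.kact_plus[j], mm * p.zeta_minus[j] * p.kact_minus[j],
                (LRG,), (LRjG,))
            # GDP/GTP exchange: ternary complex dissociates, releasing the
            # activated alpha subunit and free betagamma
            kx = p.kGTP_plus[j, t]
            if kx > 0:
                aGTP, bg = sx[f"aGTP{t+1}"], sx[f"bg{t+1}"]
                rxns.append(_Reaction(float(kx), (RjG,), (Rj, aGTP, bg)))
                kxl = p.nu_minus[t] * kx
                if kxl > 0:
                    rxns.append(_Reaction(float(kxl), (LRjG,), (LRj, aGTP, bg)))
        # G-protein cycle: hydrolysis and heterotrimer reassociation
        aGTP, aGDP, bg = sx[f"aGTP{t+1}"], sx[f"aGDP{t+1}"], sx[f"bg{t+1}"]
        rev(p.khyd_plus[t], p.khyd_minus[t], (aGTP,), (aGDP,))
        rev(p.kGRA_plus[t], p.kGRA_minus[t], (aGDP, bg), (G,))
    return rxns


class MassActionRHS:
    """Callable ``f(t, y) -> dy/dt`` compiled from the reaction network.

    In constant-ligand mode the held ligand concentration is the attribute
    ``ligand`` (M), which protocols step at ligand-addition time.  An analytic
    Jacobian is available as :meth:`jac` for stiff integrators.
    """

    def __init__(self, spec: ModelSpec, params: ParameterSet):
        params.validate(spec)
        self.spec = spec
        self.species = SpeciesIndex(spec)
        self.params = params
        self.ligand = float(params.L_conc)
        n = spec.n_species
        rxns = _build_reactions(spec, params)
        m = len(rxns)
        self._k = np.array([r.k for r in rxns])
        r1 = np.full(m, _NONE, dtype=np.int64)
        r2 = np.full(m, _NONE, dtype=np.int64)
        S = np.zeros((n, m))
        for i, r in enumerate(rxns):
            assert 1 <= len(r.reactants) <= 2
            r1[i] = r.reactants[0]
            if len(r.reactants) == 2:
                r2[i] = r.reactants[1]
            for s in r.reactants:
                if s != _LIGAND_CONST:
                    S[s, i] -= 1.0
            for s in r.products:
                if s != _LIGAND_CONST:
                    S[s, i] += 1.0
        self._r1, self._r2, self._S = r1, r2, S
        self.n_reactions = m

    def _factor(self, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
        out = np.ones(len(idx))
        mask = idx >= 0
        out[mask] = y[idx[mask]]
        out[idx == _LIGAND_CONST] = self.ligand
        return out

    def rates(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction mass-action fluxes (M/s) at state ``y``."""
        return self._k * self._factor(y, self._r1) * self._factor(y, self._r2)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        if len(y) != self.spec.n_species:
            raise ValueError(
                f"state has length {len(y)}, model dimension is {self.spec.n_species}")
        return self._S @ self.rates(np.asarray(y, dtype=float))

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        m, n = self.n_reactions, self.spec.n_species
        dv = np.zeros((m, n))
        f1 = self._factor(y, self._r1)
        f2 = self._factor(y, self._r2)
        rows = np.arange(m)
        m1 = self._r1 >= 0
        dv[rows[m1], self._r1[m1]] += (self._k * f2)[m1]
        m2 = self._r2 >= 0
        dv[rows[m2], self._r2[m2]] += (self._k * f1)[m2]
        return self._S @ dv

    def reaction_fluxes(self, y: np.ndarray) -> List[Tuple[Tuple[int, ...], Tuple[int, ...], float]]:
        """(reactants, products, flux) triples — used for flux-balance checks."""
        rxns = _build_reactions(self.spec, self.params)
        v = self.rates(np.asarray(y, dtype=float))
        return [(r.reactants, r.products, float(v[i])) for i, r in enumerate(rxns)]


def build_rhs(spec: ModelSpec, params: ParameterSet) -> MassActionRHS:
    """Construct the ODE right-hand side for ``spec`` with rates ``params``.

    Returns a callable ``f(t, y)`` (with analytic ``.jac``).  In
    constant-ligand mode ``[L]`` is held at ``f.ligand`` (initialised from
    ``params.L_conc``); in dynamic mode ``L`` is the last state entry.
    """
    return MassActionRHS(spec, params)


# ---------------------------------------------------------------------------
# state containers and aggregate pools

@dataclass
class StateVector:
    """Concentrations (M) indexed by the canonical species order, plus time (s)."""

    y: np.ndarray
    time: float = 0.0
    species: SpeciesIndex | None = None

    def __getitem__(self, name: str) -> float:
        if self.species is None:
            raise ValueError("StateVector has no species index attached")
        return float(self.y[self.species[name]])


def initial_state(spec: ModelSpec, params: ParameterSet) -> StateVector:
    """Pre-stimulation initial condition: all receptor in R, all G protein as
    heterotrimer, everything else zero (ligand at params.L_conc in dynamic mode)."""
    sx = SpeciesIndex(spec)
    y = np.zeros(spec.n_species)
    y[sx["R"]] = params.R_tot
    for t in range(spec.n_gprot):
        y[sx[f"G{t+1}"]] = params.G_tot[t]
    if spec.ligand_mode == "dynamic":
        y[sx["L"]] = params.L_conc
    return StateVector(y=y, time=0.0, species=sx)


def conservation_totals(state: StateVector | np.ndarray, spec: ModelSpec) -> Dict[str, np.ndarray]:
    """Conserved totals implied by the closed mass-action system.

    Returns total receptor, and per-pathway alpha-subunit and betagamma
    totals; all three are constant along any trajectory.
    """
    y = state.y if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    sx = SpeciesIndex(spec)
    rec = float(np.sum(y[sx.receptor_indices]))
    alpha = np.array([np.sum(y[sx.alpha_indices(t + 1)]) for t in range(spec.n_gprot)])
    bg = np.array([np.sum(y[sx.betagamma_indices(t + 1)]) for t in range(spec.n_gprot)])
    return {"receptor_total": rec, "alpha_total": alpha, "betagamma_total": bg}


def aggregate_receptor_pools(state: StateVector | np.ndarray, spec: ModelSpec,
                             pathway: int) -> Dict[str, float]:
    """Active receptor pool for one pathway, and the shared inactive pool.

    ``active_pool`` sums R*j, LR*j and all their G-coupled forms for
    j = ``pathway``; ``inactive_pool`` sums R, LR and all RG/LRG complexes.
    ``pathway`` is 1-based.
    """
    if not 1 <= pathway <= spec.n_active:
        raise ValueError(f"pathway {pathway} out of range 1..{spec.n_active}")
    y = state.y if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    sx = SpeciesIndex(spec)
    j = pathway
    act = [sx[f"R*{j}"], sx[f"LR*{j}"]]
    act += [sx[f"R*{j}G{t+1}"] for t in range(spec.n_gprot)]
    act += [sx[f"LR*{j}G{t+1}"] for t in range(spec.n_gprot)]
    inact = [sx["R"], sx["LR"]]
    inact += [sx[f"RG{t+1}"] for t in range(spec.n_gprot)]
    inact += [sx[f"LRG{t+1}"] for t in range(spec.n_gprot)]
    return {"active_pool": float(np.sum(y[act])), "inactive_pool": float(np.sum(y[inact]))}
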