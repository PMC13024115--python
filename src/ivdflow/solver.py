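"""Reduced-order transient osmo-poroelastic column solver.

The three-dimensional disc is reduced to two laterally confined axial
columns in parallel -- an NP path and an AF path, each a layered stack
BEP-CEP-core-CEP-BEP -- kinematically coupled through rigid endplates
(bottom fixed, top moves axially only).  Each element carries confined
uniaxial kinematics (J = lambda_z); the axial total stress

    sigma_total = sigma_solid(J) + sigma_fiber(J) - dpi(cF(J)) - p

is uniform along each path and matches the applied load or displacement at
the top plate.  Fluid continuity in the material frame,

    d(J)/dt = d/dZ ( k(J) dp/dZ ),

is integrated by backward Euler with a vertex-centered finite-volume
discretization, Newton iteration, and adaptive step halving.  The external
faces drain (p = 0): the disc is immersed in 0.15 M saline.

Here ``p`` is the seepage pressure relative to local osmotic equilibrium:
it vanishes at drained equilibrium, where the Donnan pressure is balanced
by solid stress alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from . import units
from .materials import (
    Environment,
    MaterialCard,
    default_environment,
    load_card,
    load_fiber_card,
)
from .population import DiscDerived
from .series import TimeSeries

__all__ = [
    "ProtocolSpec",
    "Layer",
    "ColumnPath",
    "ColumnModel",
    "ColumnConfig",
    "SolverConfig",
    "SolverState",
    "ColumnSolver",
    "Segment",
    "History",
    "EquilibriumResult",
    "SolverFailure",
    "ConvergenceError",
    "build_column",
    "equilibrium_0d",
    "equilibrium_at_displacement",
    "equilibrate_free",
    "equilibrate_preload",
    "free_swelling_segments",
    "preload_segments",
    "default_protocols",
    "run_protocol",
    "swelling_protocol",
    "creep_protocol",
    "relaxation_protocol",
    "terzaghi_reference",
    "HOLD_DURATION",
]

#: default hold duration: 30 h in seconds
HOLD_DURATION = 30 * 3600.0


class SolverFailure(RuntimeError):
    """Newton failed to converge even at the minimum time step."""


class ConvergenceError(RuntimeError):
    """A root-finding bracket could not be established."""


# ---------------------------------------------------------------------------
# model description


@dataclass(frozen=True)
class Layer:
    """One axial layer of a column path."""

    card: MaterialCard
    thickness: float  # mm
    n_nodes: int  # axial node count; elements = n_nodes - 1
    solid: str = "holmes_mow"  # or "neo_hookean"
    constant_permeability: bool = False
    fiber_modulus: float = 0.0  # additive linear axial stiffness (tension only), MPa

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("each layer needs at least 2 nodes")
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        if self.solid not in ("holmes_mow", "neo_hookean"):
            raise ValueError(f"unknown solid model {self.solid!r}")


@dataclass(frozen=True)
class ColumnPath:
    name: str
    area: float  # mm^2
    layers: tuple[Layer, ...]
    lateral_leak: float = 0.0  # 1/(MPa s); optional peripheral drainage sink

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("path area must be > 0")


@dataclass(frozen=True)
class ColumnModel:
    paths: tuple[ColumnPath, ...]
    condition: str = "healthy"
    environment: Environment = field(default_factory=default_environment)
    geometry: Optional[DiscDerived] = None

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.paths)


@dataclass(frozen=True)
class ColumnConfig:
    """Discretization and reduction options for the disc column."""

    n_nodes_bep: int = 2
    n_nodes_cep: int = 3
    n_nodes_core: int = 10
    af_lateral_leak: float = 0.0  # off by default; first-order peripheral drainage
    #: tension-only axial restraint on the NP/AF cores, MPa.  Surrogate for
    #: the hoop fiber tension and lateral constraint that limit axial
    #: swelling in the 3D disc; sized so healthy free swelling settles near
    #: the literature-typical ~10 % axial strain.  Identical for both
    #: conditions (fiber properties do not change with degeneration).
    core_tension_modulus: float = 2.0

    def __post_init__(self) -> None:
        for n in (self.n_nodes_bep, self.n_nodes_cep, self.n_nodes_core):
            if n < 2:
                raise ValueError("node counts must be >= 2 per layer")


@dataclass(frozen=True)
class SolverConfig:
    newton_tol: float = 1e-10  # relative on the residual norm
    newton_abs_tol: float = 1e-13
    newton_max_iter: int = 25
    polish_iterations: int = 1  # extra Newton steps after convergence
    ramp_steps: int = 20
    dt_init: float = 1.0  # s, first hold step
    dt_growth: float = 1.2
    dt_max: float = 600.0  # s
    dt_min: float = 1e-6  # s; below this a rejected step is fatal
    lam_min_margin: float = 1e-3  # keep J > phi0s + margin
    lam_max: float = 6.0


@dataclass(frozen=True)
class ProtocolSpec:
    """A loading schedule of the standard protocol roster.

    kind='swelling': free swelling (preload 0) or swelling under a small
    constant preload (20 or 50 N, ramped at 1 N/s).
    kind='creep': ramp from the 20 N preload to `target` newtons.
    kind='relaxation': ramp to `target` engineering strain (fraction of
    disc height, compressive) from the 50 N preload.
    """

    kind: str
    preload: float = 0.0  # N
    target: float = 0.0  # N (creep) or strain fraction (relaxation)
    ramp_duration: float = 1.0  # s
    hold_duration: float = HOLD_DURATION  # s
    output_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("swelling", "creep", "relaxation"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind in ("creep", "relaxation"):
            if self.ramp_duration <= 0:
                raise ValueError("ramp_duration must be > 0 for loaded protocols")
            if self.target <= 0:
                raise ValueError("protocol target must be positive")
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be > 0")

    @property
    def label(self) -> str:
        if self.kind == "swelling":
            return f"swelling_{int(self.preload)}N"
        if self.kind == "creep":
            return f"creep_{int(self.target)}N"
        return f"relaxation_{int(round(self.target * 100))}pct"


def swelling_protocol(preload: float = 0.0) -> ProtocolSpec:
    return ProtocolSpec(kind="swelling", preload=preload)


#: Table of creep ramp durations: load ramps take 1 s per 500 N step.
_CREEP_RAMPS = {500.0: 1.0, 1000.0: 2.0, 1500.0: 3.0}
#: Relaxation strain ramps.  The laterally confined column has no
#: isochoric deformation mode, so imposed displacement must be matched by
#: fluid efflux; the drainage capacity of the endplate route is choke
#: limited at roughly 1e-3 mm/s per draining face (the compacting boundary
#: layer's permeability falls as fast as its Donnan pressure rises).  The
#: nominal 1 %/s laboratory ramps are therefore infeasible for this
#: reduction and are applied at 1/300 of that rate, still two orders of
#: magnitude shorter than the 30 h hold they precede.
_RELAX_RAMPS = {0.05: 1500.0, 0.10: 3000.0, 0.15: 4500.0}


def creep_protocol(load: float) -> ProtocolSpec:
    ramp = _CREEP_RAMPS.get(float(load), max(load / 500.0, 1.0))
    return ProtocolSpec(kind="creep", preload=20.0, target=float(load), ramp_duration=ramp)


def relaxation_protocol(strain: float) -> ProtocolSpec:
    ramp = _RELAX_RAMPS.get(float(strain), max(strain * 3.0e4, 1.0))
    return ProtocolSpec(kind="relaxation", preload=50.0, target=float(strain), ramp_duration=ramp)


def default_protocols() -> list[ProtocolSpec]:
    """The seven-protocol study roster."""
    return (
        [swelling_protocol(0.0)]
        + [creep_protocol(f) for f in (500.0, 1000.0, 1500.0)]
        + [relaxation_protocol(s) for s in (0.05, 0.10, 0.15)]
    )


# ---------------------------------------------------------------------------
# model construction


def _af_effective_card(condition: str, fractions: Sequence[float]) -> MaterialCard:
    """Average the lamella-resolved AF transport/FCD gradients over the
    twenty radial stations into one effective core card."""
    cards = [load_card("AF", condition, lamella_fraction=f) for f in fractions]
    base = cards[0]
    return replace(
        base,
        k0=float(np.mean([c.k0 for c in cards])),
        phi0w=float(np.mean([c.phi0w for c in cards])),
        cf0=float(np.mean([c.cf0 for c in cards])),
        af_inner_outer=base.af_inner_outer,
    )


def build_column(
    geom: DiscDerived,
    condition: str,
    config: ColumnConfig = ColumnConfig(),
    environment: Optional[Environment] = None,
) -> ColumnModel:
    """Two-path disc column (NP and AF in parallel over their areas)."""
    if condition not in ("healthy", "degenerated"):
        raise ValueError(f"unknown condition {condition!r}")
    env = environment if environment is not None else default_environment()
    bep = load_card("BEP", condition)
    cep = load_card("CEP", condition)
    np_card = load_card("NP", condition)
    af_card = _af_effective_card(condition, geom.lamella_fractions)
    cep_fiber = load_fiber_card("CEP-axial")
    efa = cep_fiber.Ef_a if cep_fiber.Ef_a is not None else 0.0

    def stack(core_card: MaterialCard) -> tuple[Layer, ...]:
        bep_layer = Layer(
            card=bep,
            thickness=geom.bep_thickness,
            n_nodes=config.n_nodes_bep,
            solid="neo_hookean",
            constant_permeability=True,
        )
        cep_layer = Layer(
            card=cep,
            thickness=geom.cep_thickness,
            n_nodes=config.n_nodes_cep,
            fiber_modulus=efa,
        )
        core = Layer(
            card=core_card,
            thickness=geom.core_height,
            n_nodes=config.n_nodes_core,
            fiber_modulus=config.core_tension_modulus,
        )
        return (bep_layer, cep_layer, core, cep_layer, bep_layer)

    paths = (
        ColumnPath(name="NP", area=geom.np_area, layers=stack(np_card)),
        ColumnPath(
            name="AF",
            area=geom.af_area,
            layers=stack(af_card),
            lateral_leak=config.af_lateral_leak,
        ),
    )
    return ColumnModel(paths=paths, condition=condition, environment=env, geometry=geom)


# ---------------------------------------------------------------------------
# discretization


class _Discretization:
    """Flat element/node arrays for all paths, plus assembly index maps."""

    def __init__(self, model: ColumnModel):
        self.model = model
        env = model.environment
        self.RT_mpa = env.R * env.T * 1e-6  # MPa per (mol/m^3)
        self.c0 = units.concentration_to_si(env.c0)

        L, path_of, n_lo, n_hi = [], [], [], []
        is_nh, HA, lame_lam, lame_mu = [], [], [], []
        beta_m, Mperm, kconst, k0mm, phi0w, cf0_abs, Phi_osm, fibE, leak = (
            [], [], [], [], [], [], [], [], [])
        node_count = 0
        self.path_first_node, self.path_last_node = [], []
        self.path_elems = []

        for path in model.paths:
            first_node = node_count
            e_first = len(L)
            for layer in path.layers:
                m = layer.n_nodes - 1
                he = layer.thickness / m
                c = layer.card
                lam_c, mu_c = c.lame
                for _ in range(m):
                    n_lo.append(node_count)
                    n_hi.append(node_count + 1)
                    node_count += 1
                    L.append(he)
                    path_of.append(len(self.path_first_node))
                    is_nh.append(layer.solid == "neo_hookean")
                    HA.append(c.HA)
                    lame_lam.append(lam_c)
                    lame_mu.append(mu_c)
                    beta_m.append(c.beta_m)
                    Mperm.append(c.M)
                    kconst.append(layer.constant_permeability)
                    k0mm.append(c.k0_mm)
                    phi0w.append(c.phi0w)
                    cf0_abs.append(abs(c.cf0))
                    Phi_osm.append(c.Phi)
                    fibE.append(layer.fiber_modulus)
                    leak.append(path.lateral_leak)
            node_count += 1  # top node of the path
            self.path_first_node.append(first_node)
            self.path_last_node.append(node_count - 1)
            self.path_elems.append(np.arange(e_first, len(L)))

        self.E = len(L)
        self.N = node_count
        self.S = len(model.paths)
        self.L = np.array(L)
        self.path_of_elem = np.array(path_of, dtype=int)
        self.n_lo = np.array(n_lo, dtype=int)
        self.n_hi = np.array(n_hi, dtype=int)
        self.is_nh = np.array(is_nh, dtype=bool)
        self.HA = np.array(HA)
        self.lame_lam = np.array(lame_lam)
        self.lame_mu = np.array(lame_mu)
        self.beta_m = np.array(beta_m)
        self.Mperm = np.array(Mperm)
        self.kconst = np.array(kconst, dtype=bool)
        self.k0mm = np.array(k0mm)
        self.phi0w = np.array(phi0w)
        self.phi0s = 1.0 - self.phi0w
        self.cf0_abs = np.array(cf0_abs)
        self.Phi_osm = np.array(Phi_osm)
        self.fibE = np.array(fibE)
        self.leak = np.array(leak)
        self.areas = np.array([p.area for p in model.paths])

        # pressure dofs: every node except the two outer (draining) nodes of
        # each path
        pdof = np.full(self.N, -1, dtype=int)
        nxt = 0
        boundary = set(self.path_first_node) | set(self.path_last_node)
        for n in range(self.N):
            if n not in boundary:
                pdof[n] = nxt
                nxt += 1
        self.pdof = pdof
        self.P = nxt
        self.n = self.E + self.P + self.S

        # interior-node continuity maps: for pressure dof d at node i, the
        # elements left and right of i (contiguous numbering per path)
        self.int_nodes = np.array([n for n in range(self.N) if pdof[n] >= 0], dtype=int)
        node_to_left_elem = np.full(self.N, -1, dtype=int)
        node_to_right_elem = np.full(self.N, -1, dtype=int)
        for e in range(self.E):
            node_to_right_elem[self.n_lo[e]] = e
            node_to_left_elem[self.n_hi[e]] = e
        self.le = node_to_left_elem[self.int_nodes]
        self.re = node_to_right_elem[self.int_nodes]
        self.leak_cv = 0.5 * (
            self.leak[self.le] * self.L[self.le] + self.leak[self.re] * self.L[self.re]
        )

        # matrix mapping element stretches to per-path top displacement
        self.Umat = np.zeros((self.S, self.E))
        for s, elems in enumerate(self.path_elems):
            self.Umat[s, elems] = self.L[elems]

        self.sig_cols = self.E + self.P + np.arange(self.S)
        self._J = np.zeros((self.n, self.n))

        # residual row scales for a dimensionless convergence norm:
        # stress rows -> strain units, continuity rows -> stretch-increment
        # units (x dt inside step), coupling rows -> strain units
        self.w_stress = 1.0 / np.maximum(self.HA + self.fibE, 1.0)
        self.cv_len = 0.5 * (self.L[self.le] + self.L[self.re])
        total_h = np.array([self.L[el].sum() for el in self.path_elems])
        self.w_couple = np.concatenate(
            [[1.0 / (self.areas.sum() * 1.0)], 1.0 / total_h[1:]]
        )
        self.w_couple_disp = 1.0 / total_h

    # -- pointwise laws (vectorized over elements) --------------------------

    def solid_stress(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """sigma(lam) and d sigma/d lam for every element."""
        lam = np.asarray(lam)
        sig = np.empty_like(lam)
        dsig = np.empty_like(lam)
        hm = ~self.is_nh
        if np.any(hm):
            l = lam[hm]
            b = self.beta_m[hm]
            ha = self.HA[hm]
            f = l - 1.0 / l
            fp = 1.0 + 1.0 / l**2
            g = l**2 - 1.0 - 2.0 * np.log(l)
            gp = 2.0 * l - 2.0 / l
            eb = np.exp(b * g)
            sig[hm] = 0.5 * ha * f * eb
            dsig[hm] = 0.5 * ha * eb * (fp + b * f * gp)
        if np.any(self.is_nh):
            l = lam[self.is_nh]
            mu = self.lame_mu[self.is_nh]
            la = self.lame_lam[self.is_nh]
            sig[self.is_nh] = mu * (l**2 - 1.0) / l + la * np.log(l) / l
            dsig[self.is_nh] = mu * (1.0 + 1.0 / l**2) + la * (1.0 - np.log(l)) / l**2
        # additive tension-only linear fiber stiffness (CEP axial modulus)
        tens = lam > 1.0
        sig = sig + np.where(tens, self.fibE * (lam - 1.0), 0.0)
        dsig = dsig + np.where(tens, self.fibE, 0.0)
        return sig, dsig

    def osmotic(self, lam: np.ndarray, fcd_scale: float) -> tuple[np.ndarray, np.ndarray]:
        """Donnan pressure dpi(lam) (MPa) and d dpi/d lam."""
        denom = lam - 1.0 + self.phi0w
        cF = fcd_scale * self.cf0_abs * self.phi0w / denom
        root = np.sqrt(cF**2 + 4.0 * self.c0**2)
        dpi = self.Phi_osm * self.RT_mpa * (root - 2.0 * self.c0)
        ddpi = self.Phi_osm * self.RT_mpa * (cF / root) * (-cF / denom)
        return dpi, ddpi

    def permeability(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """k(lam) in mm^4/(N s) and dk/d lam."""
        k = np.empty_like(lam)
        dk = np.empty_like(lam)
        const = self.kconst
        k[const] = self.k0mm[const]
        dk[const] = 0.0
        v = ~const
        if np.any(v):
            l = lam[v]
            ps = self.phi0s[v]
            bm = self.beta_m[v]
            M = self.Mperm[v]
            kv = self.k0mm[v] * ((l - ps) / (1.0 - ps)) ** bm * np.exp(M * (l**2 - 1.0) / 2.0)
            k[v] = kv
            dk[v] = kv * (bm / (l - ps) + M * l)
        return k, dk

    # -- assembly ------------------------------------------------------------

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return x[: self.E], x[self.E : self.E + self.P], x[self.E + self.P :]

    def full_pressure(self, pint: np.ndarray) -> np.ndarray:
        p = np.zeros(self.N)
        p[self.int_nodes] = pint
        return p

    def residual_and_jac(
        self,
        x: np.ndarray,
        lam_old: np.ndarray,
        dt: float,
        mode: str,
        value: float,
        fcd_scale: float,
        want_jac: bool = True,
    ) -> tuple[np.ndarray, Optional[np.ndarray]]:
        lam, pint, sig = self.split(x)
        p = self.full_pressure(pint)
        sig_s, dsig = self.solid_stress(lam)
        dpi, ddpi = self.osmotic(lam, fcd_scale)
        k, dk = self.permeability(lam)

        R = np.zeros(self.n)
        # stress rows
        pbar = 0.5 * (p[self.n_lo] + p[self.n_hi])
        R[: self.E] = sig_s - dpi - pbar - sig[self.path_of_elem]

        # continuity rows
        i = self.int_nodes
        le, re = self.le, self.re
        Ll, Lr = self.L[le], self.L[re]
        p_i = p[i]
        p_im = p[i - 1]
        p_ip = p[i + 1]
        R[self.E : self.E + self.P] = (
            0.5 * Ll * (lam[le] - lam_old[le]) / dt
            + 0.5 * Lr * (lam[re] - lam_old[re]) / dt
            - k[re] * (p_ip - p_i) / Lr
            + k[le] * (p_i - p_im) / Ll
            + self.leak_cv * p_i
        )

        # coupling rows
        u = self.Umat @ (lam - 1.0)
        crow = self.E + self.P
        if mode == "force":
            R[crow] = self.areas @ sig + value
            for s in range(1, self.S):
                R[crow + s] = u[s] - u[0]
        elif mode == "disp":
            for s in range(self.S):
                R[crow + s] = u[s] - value
        else:  # pragma: no cover - guarded upstream
            raise ValueError(f"unknown control mode {mode!r}")

        if not want_jac:
            return R, None

        J = self._J
        J[...] = 0.0
        erow = np.arange(self.E)
        J[erow, erow] = dsig - ddpi
        lo_d = self.pdof[self.n_lo]
        hi_d = self.pdof[self.n_hi]
        m = lo_d >= 0
        J[erow[m], self.E + lo_d[m]] += -0.5
        m = hi_d >= 0
        J[erow[m], self.E + hi_d[m]] += -0.5
        J[erow, self.sig_cols[self.path_of_elem]] = -1.0

        rrow = self.E + np.arange(self.P)
        J[rrow, le] = 0.5 * Ll / dt + dk[le] * (p_i - p_im) / Ll
        J[rrow, re] += 0.5 * Lr / dt - dk[re] * (p_ip - p_i) / Lr
        J[rrow, self.E + self.pdof[i]] = k[le] / Ll + k[re] / Lr + self.leak_cv
        d_im = self.pdof[i - 1]
        m = d_im >= 0
        J[rrow[m], self.E + d_im[m]] += -k[le][m] / Ll[m]
        d_ip = self.pdof[i + 1]
        m = d_ip >= 0
        J[rrow[m], self.E + d_ip[m]] += -k[re][m] / Lr[m]

        if mode == "force":
            J[crow, self.sig_cols] = self.areas
            for s in range(1, self.S):
                J[crow + s, self.path_elems[s]] = self.L[self.path_elems[s]]
                J[crow + s, self.path_elems[0]] = -self.L[self.path_elems[0]]
        else:
            for s in range(self.S):
                J[crow + s, self.path_elems[s]] = self.L[self.path_elems[s]]
        return R, J


# ---------------------------------------------------------------------------
# state and stepping


@dataclass
class SolverState:
    """Converged solution at one time: elementwise stretch J = lam, full
    nodal seepage pressure p (MPa, zero on draining boundaries), per-path
    axial total stress sigma (MPa)."""

    t: float
    lam: np.ndarray
    p: np.ndarray
    sigma: np.ndarray
    u_top: float = 0.0
    reaction_force: float = 0.0
    fcd_scale: float = 1.0

    def copy(self) -> "SolverState":
        return SolverState(
            t=self.t,
            lam=self.lam.copy(),
            p=self.p.copy(),
            sigma=self.sigma.copy(),
            u_top=self.u_top,
            reaction_force=self.reaction_force,
            fcd_scale=self.fcd_scale,
        )


@dataclass(frozen=True)
class Segment:
    """A control segment: linear ramp (or hold) of the boundary condition
    and the fixed-charge activation factor over ``duration`` seconds."""

    mode: str  # 'force' (N, compressive positive) or 'disp' (mm, top plate)
    start: float
    end: float
    duration: float
    n_steps: Optional[int] = None  # uniform steps; None -> adaptive policy
    fcd_start: float = 1.0
    fcd_end: float = 1.0


@dataclass
class History:
    t: np.ndarray
    u_top: np.ndarray
    force: np.ndarray
    final_state: SolverState


class ColumnSolver:
    """Backward-Euler Newton solver for a :class:`ColumnModel`."""

    def __init__(self, model: ColumnModel, config: SolverConfig = SolverConfig()):
        self.model = model
        self.config = config
        self.disc = _Discretization(model)

    # -- state helpers -------------------------------------------------------

    def initial_state(self) -> SolverState:
        d = self.disc
        return SolverState(
            t=0.0,
            lam=np.ones(d.E),
            p=np.zeros(d.N),
            sigma=np.zeros(d.S),
            fcd_scale=0.0,
        )

    def u_top(self, state: SolverState) -> float:
        return float((self.disc.Umat @ (state.lam - 1.0))[0])

    def reaction(self, state: SolverState) -> float:
        """Compressive reaction force at the top plate, N."""
        return float(-(self.disc.areas @ state.sigma))

    def displacement_profile(self, state: SolverState) -> list[np.ndarray]:
        """Nodal axial displacement per path, measured from the fixed base."""
        out = []
        for elems in self.disc.path_elems:
            du = self.disc.L[elems] * (state.lam[elems] - 1.0)
            out.append(np.concatenate([[0.0], np.cumsum(du)]))
        return out

    # -- core step -----------------------------------------------------------

    def step(
        self,
        state: SolverState,
        dt: float,
        mode: str,
        value: float,
        fcd_scale: float = 1.0,
    ) -> SolverState:
        """One backward-Euler step; raises SolverFailure on Newton failure."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        d = self.disc
        cfg = self.config
        x = np.concatenate([state.lam, state.p[d.int_nodes], state.sigma])
        lam_old = state.lam
        lam_floor = d.phi0s + cfg.lam_min_margin

        # dimensionless residual weights (continuity rows scale with dt)
        w = np.concatenate(
            [
                d.w_stress,
                dt / d.cv_len,
                d.w_couple if mode == "force" else d.w_couple_disp,
            ]
        )

        def scaled_norm(R: np.ndarray) -> float:
            return float(np.linalg.norm(w * R))

        r0_norm = None
        converged = False
        polish_left = cfg.polish_iterations
        for _ in range(cfg.newton_max_iter):
            R, J = d.residual_and_jac(x, lam_old, dt, mode, value, fcd_scale)
            rn = scaled_norm(R)
            if r0_norm is None:
                r0_norm = max(rn, 1e-30)
            if rn <= max(cfg.newton_tol * r0_norm, cfg.newton_abs_tol):
                converged = True
                if polish_left <= 0 or rn == 0.0:
                    break
                polish_left -= 1
            try:
                dx = np.linalg.solve(J, -R)
            except np.linalg.LinAlgError as exc:
                raise SolverFailure(f"singular Jacobian at t={state.t + dt:.3g}") from exc
            if converged is False and np.linalg.norm(dx) <= 1e-13 * (1.0 + np.linalg.norm(x)):
                # update below the representable floor: accept
                converged = True
                break
            x = x + dx
            # project stretches back into the admissible box; compaction
            # boundary layers push individual elements toward the solid
            # volume floor where the Donnan term diverges
            np.clip(x[: d.E], lam_floor, cfg.lam_max, out=x[: d.E])
        else:
            R, _ = d.residual_and_jac(x, lam_old, dt, mode, value, fcd_scale, want_jac=False)
            rn = scaled_norm(R)
            if rn > max(cfg.newton_tol * r0_norm, cfg.newton_abs_tol):
                raise SolverFailure(
                    f"Newton stalled (|R|={rn:.3e}) at t={state.t + dt:.3g}, dt={dt:.3g}"
                )
            converged = True
        if not converged:  # pragma: no cover - defensive
            raise SolverFailure("Newton did not converge")

        lam, pint, sig = d.split(x)
        new = SolverState(
            t=state.t + dt,
            lam=lam.copy(),
            p=d.full_pressure(pint),
            sigma=sig.copy(),
            fcd_scale=fcd_scale,
        )
        new.u_top = self.u_top(new)
        new.reaction_force = value if mode == "force" else self.reaction(new)
        return new

    def mass_balance_residual(
        self, old: SolverState, new: SolverState, dt: float
    ) -> list[tuple[float, float]]:
        """Per-path (content change, net boundary influx*dt), both in mm of
        fluid column.  The interior fluid-content change (boundary half
        cells excluded, their exchange being part of the boundary flux)
        must equal the net influx through the draining faces."""
        d = self.disc
        k, _ = d.permeability(new.lam)
        out = []
        for s, elems in enumerate(d.path_elems):
            e0, eN = elems[0], elems[-1]
            dl = new.lam - old.lam
            lhs = float(
                np.sum(d.L[elems] * dl[elems])
                - 0.5 * d.L[e0] * dl[e0]
                - 0.5 * d.L[eN] * dl[eN]
            )
            n_first = d.path_first_node[s]
            n_last = d.path_last_node[s]
            # Darcy influx through the faces bounding the interior region
            influx = (
                -k[e0] * (new.p[n_first + 1] - new.p[n_first]) / d.L[e0]
                + k[eN] * (new.p[n_last] - new.p[n_last - 1]) / d.L[eN]
            )
            leak_loss = 0.0
            if np.any(d.leak):
                in_path = (d.int_nodes >= n_first) & (d.int_nodes <= n_last)
                leak_loss = float(np.sum(d.leak_cv[in_path] * new.p[d.int_nodes[in_path]]))
            out.append((lhs, dt * (influx - leak_loss)))
        return out

    # -- time integration ----------------------------------------------------

    def simulate(
        self,
        segments: Sequence[Segment],
        state: Optional[SolverState] = None,
        record: bool = True,
    ) -> History:
        cfg = self.config
        st = state.copy() if state is not None else self.initial_state()
        ts, us, fs = [st.t], [self.u_top(st)], [self.reaction(st)]

        for seg in segments:
            tau = 0.0
            if seg.n_steps is not None:
                dt_nom = seg.duration / seg.n_steps
                dt = dt_nom
                adaptive = False
            else:
                dt = cfg.dt_init
                adaptive = True

            while tau < seg.duration - 1e-9 * seg.duration:
                dt_try = min(dt, seg.duration - tau)
                while True:
                    frac = (tau + dt_try) / seg.duration
                    value = seg.start + (seg.end - seg.start) * frac
                    fcd = seg.fcd_start + (seg.fcd_end - seg.fcd_start) * frac
                    try:
                        st_new = self.step(st, dt_try, seg.mode, value, fcd)
                        break
                    except SolverFailure:
                        dt_try *= 0.5
                        if dt_try < cfg.dt_min:
                            raise
                tau += dt_try
                st = st_new
                if record:
                    ts.append(st.t)
                    us.append(st.u_top)
                    fs.append(st.reaction_force if seg.mode == "force" else self.reaction(st))
                if adaptive:
                    dt = min(max(dt_try, dt) * cfg.dt_growth, cfg.dt_max)
                else:
                    dt = dt_nom
        return History(
            t=np.array(ts), u_top=np.array(us), force=np.array(fs), final_state=st
        )


# ---------------------------------------------------------------------------
# equilibrium (0D oracle)


@dataclass(frozen=True)
class EquilibriumResult:
    u_top: float  # mm, top-plate displacement from reference
    core_stretch: float  # area-weighted mean stretch of the soft cores
    sigma_paths: np.ndarray  # MPa
    force: float  # N, compressive
    lam: np.ndarray  # per-element stretches


# bracketed path-stress range, MPa: far beyond the study's compressive
# loads; mild tension (paths only see tension near free swelling, ~0.1 MPa)
_SIG_LO, _SIG_HI = -500.0, 5.0


def _lam_of_sigma(disc: _Discretization, e: int, sigma: float, fcd_scale: float) -> float:
    lo = disc.phi0s[e] + 1e-9
    hi = 8.0

    def g(lam: float) -> float:
        arr = np.full(disc.E, 1.0)
        arr[e] = lam
        s, _ = disc.solid_stress(arr)
        dpi, _ = disc.osmotic(arr, fcd_scale)
        return float(s[e] - dpi[e]) - sigma

    a, b = lo * 1.0 + 1e-6, hi
    ga, gb = g(a), g(b)
    # saturate at the bracket edges: probing stresses beyond what the
    # element can reach (e.g. an uncharged solid compressed to -500 MPa)
    # clamps to the edge, keeping path displacement monotone and total
    if ga > 0:
        return a
    if gb < 0:
        return b
    return brentq(g, a, b, xtol=1e-13, rtol=8.9e-16)


def _path_u_of_sigma(
    disc: _Discretization, s: int, sigma: float, fcd_scale: float
) -> tuple[float, np.ndarray]:
    elems = disc.path_elems[s]
    lam = np.empty(len(elems))
    cache: dict[tuple, float] = {}
    for idx, e in enumerate(elems):
        key = (
            disc.is_nh[e], disc.HA[e], disc.beta_m[e], disc.phi0w[e],
            disc.cf0_abs[e], disc.fibE[e], disc.lame_mu[e],
        )
        if key not in cache:
            cache[key] = _lam_of_sigma(disc, e, sigma, fcd_scale)
        lam[idx] = cache[key]
    return float(np.sum(disc.L[elems] * (lam - 1.0))), lam


def _sigma_of_u(disc: _Discretization, s: int, u: float, fcd_scale: float) -> float:
    def h(sigma: float) -> float:
        return _path_u_of_sigma(disc, s, sigma, fcd_scale)[0] - u

    return brentq(h, _SIG_LO, _SIG_HI, xtol=1e-12, rtol=8.9e-16)


def _equilibrium_result(
    solver_disc: _Discretization, u: float, fcd_scale: float
) -> EquilibriumResult:
    d = solver_disc
    sigmas = np.empty(d.S)
    lam = np.ones(d.E)
    for s in range(d.S):
        sigmas[s] = _sigma_of_u(d, s, u, fcd_scale)
        _, lam_p = _path_u_of_sigma(d, s, sigmas[s], fcd_scale)
        lam[d.path_elems[s]] = lam_p
    # area-weighted mean stretch over elements with nonzero FCD core (soft
    # core = Holmes-Mow elements that are neither CEP nor BEP: identify by
    # largest per-path layer, i.e. elements with maximal count of equal L)
    core_mask = np.zeros(d.E, dtype=bool)
    for s, elems in enumerate(d.path_elems):
        # the core is the thickest contiguous block; for built disc columns
        # it is the block with the most elements
        Ls = d.L[elems]
        vals, counts = np.unique(np.round(Ls, 12), return_counts=True)
        core_L = vals[np.argmax(counts * vals)]
        core_mask[elems] = np.isclose(d.L[elems], core_L)
    w = d.areas[d.path_of_elem] * core_mask
    core_stretch = float(np.sum(w * lam) / np.sum(w)) if np.sum(w) > 0 else float("nan")
    force = float(-(d.areas @ sigmas))
    return EquilibriumResult(
        u_top=u, core_stretch=core_stretch, sigma_paths=sigmas, force=force, lam=lam
    )


def equilibrium_0d(
    model: ColumnModel,
    applied_force: float = 0.0,
    fcd_scale: float = 1.0,
) -> EquilibriumResult:
    """Drained equilibrium under a compressive force (0 = free swelling).

    At equilibrium the seepage pressure vanishes, so each element satisfies
    sigma_solid(lam) - dpi(cF(lam)) = sigma_path, the per-path stresses
    share the top displacement, and sum_paths A sigma = -F.  Solved by
    nested bracketed root finding (brentq), independent of the transient
    solver path.
    """
    if applied_force < 0:
        raise ValueError("applied_force is compressive and must be >= 0")
    d = _Discretization(model)

    def net(u: float) -> float:
        return sum(d.areas[s] * _sigma_of_u(d, s, u, fcd_scale) for s in range(d.S)) + applied_force

    # the admissible displacement window is the intersection of what each
    # path can reach over the bracketed stress range
    eps = 1e-7
    u_lo = max(_path_u_of_sigma(d, s, _SIG_LO * (1 - eps), fcd_scale)[0] for s in range(d.S)) + eps
    u_hi = min(_path_u_of_sigma(d, s, _SIG_HI * (1 - eps), fcd_scale)[0] for s in range(d.S)) - eps
    f_lo, f_hi = net(u_lo), net(u_hi)
    if f_lo > 0 or f_hi < 0:
        raise ConvergenceError("equilibrium displacement outside the bracket")
    u = brentq(net, u_lo, u_hi, xtol=1e-12, rtol=8.9e-16)
    return _equilibrium_result(d, u, fcd_scale)


def equilibrium_at_displacement(
    model: ColumnModel, u_top: float, fcd_scale: float = 1.0
) -> EquilibriumResult:
    """Drained equilibrium with the top plate held at ``u_top`` mm."""
    return _equilibrium_result(_Discretization(model), u_top, fcd_scale)


# ---------------------------------------------------------------------------
# protocols


def _default_output_times(protocol: ProtocolSpec) -> np.ndarray:
    times = np.geomspace(1.0, protocol.hold_duration, 200)
    extra = [protocol.ramp_duration, protocol.ramp_duration + protocol.hold_duration]
    if protocol.kind == "swelling" and protocol.preload > 0:
        extra.append(protocol.preload / 1.0)  # 1 N/s preload ramp endpoint
    return np.unique(np.concatenate([times, np.array(extra)]))


def free_swelling_segments(hold: float = HOLD_DURATION) -> list[Segment]:
    """30 h immersion: fixed charge activated over 1 s, then free hold."""
    return [
        Segment("force", 0.0, 0.0, 1.0, n_steps=5, fcd_start=0.0, fcd_end=1.0),
        Segment("force", 0.0, 0.0, hold),
    ]


def preload_segments(preload: float, hold: float = HOLD_DURATION) -> list[Segment]:
    """Ramp to the preload at 1 N/s, then hold to equilibrium."""
    return [
        Segment("force", 0.0, preload, preload / 1.0, n_steps=20),
        Segment("force", preload, preload, hold),
    ]


def equilibrate_free(solver: ColumnSolver) -> SolverState:
    return solver.simulate(free_swelling_segments(), record=False).final_state


def equilibrate_preload(solver: ColumnSolver, preload: float, state: SolverState) -> SolverState:
    return solver.simulate(preload_segments(preload), state=state, record=False).final_state


def run_protocol(
    model: ColumnModel | ColumnSolver,
    protocol: ProtocolSpec,
    config: SolverConfig = SolverConfig(),
    start_state: Optional[SolverState] = None,
) -> TimeSeries:
    """Execute one protocol and sample its measured response.

    The 30 h free-swelling pre-equilibration (and, for creep/relaxation,
    the 20/50 N preload equilibration) precede the measured phase; pass
    ``start_state`` (from :func:`equilibrate_free` /
    :func:`equilibrate_preload`) to reuse cached pre-stages.

    Returns displacement (swelling: swelling displacement, positive up;
    creep: compressive displacement from the measured-phase start, positive
    down) or reaction force (relaxation, compressive positive), on a
    log-spaced grid over the hold.
    """
    solver = model if isinstance(model, ColumnSolver) else ColumnSolver(model, config)
    times = (
        np.asarray(protocol.output_times)
        if protocol.output_times is not None
        else _default_output_times(protocol)
    )

    meta = {
        "protocol": protocol.label,
        "kind": protocol.kind,
        "preload_N": protocol.preload,
        "target": protocol.target,
        "ramp_duration_s": protocol.ramp_duration,
        "condition": solver.model.condition,
    }

    if protocol.kind == "swelling":
        if start_state is None:
            segs = free_swelling_segments(protocol.hold_duration)
            if protocol.preload > 0:
                segs = free_swelling_segments() + preload_segments(
                    protocol.preload, protocol.hold_duration
                )
            hist = solver.simulate(segs)
            t0 = 0.0 if protocol.preload == 0 else HOLD_DURATION + 1.0
        else:
            if protocol.preload == 0:
                raise ValueError("free swelling always starts from the reference state")
            hist = solver.simulate(
                preload_segments(protocol.preload, protocol.hold_duration), state=start_state
            )
            t0 = start_state.t
        u0 = np.interp(t0, hist.t, hist.u_top)
        tt = hist.t - t0
        vals = np.interp(times, tt, hist.u_top)
        meta["t_hold_start_s"] = 1.0 if protocol.preload == 0 else protocol.preload / 1.0
        meta["u_reference_mm"] = float(u0)
        ts = TimeSeries(t=times, value=vals, channel="axial_displacement", metadata=meta)

    elif protocol.kind == "creep":
        if start_state is None:
            s0 = equilibrate_free(solver)
            start_state = equilibrate_preload(solver, protocol.preload, s0)
        u_pre = solver.u_top(start_state)
        segs = [
            Segment(
                "force", protocol.preload, protocol.target, protocol.ramp_duration,
                n_steps=max(config.ramp_steps, 20),
            ),
            Segment("force", protocol.target, protocol.target, protocol.hold_duration),
        ]
        hist = solver.simulate(segs, state=start_state)
        tt = hist.t - start_state.t
        u_c = u_pre - hist.u_top  # compressive displacement, positive down
        vals = np.interp(times, tt, u_c)
        meta["t_hold_start_s"] = protocol.ramp_duration
        meta["u_preload_mm"] = float(u_pre)
        ts = TimeSeries(t=times, value=vals, channel="axial_displacement", metadata=meta)

    else:  # relaxation
        if start_state is None:
            s0 = equilibrate_free(solver)
            start_state = equilibrate_preload(solver, protocol.preload, s0)
        u_pre = solver.u_top(start_state)
        height = (
            solver.model.geometry.mean_height
            if solver.model.geometry is not None
            else sum(l.thickness for l in solver.model.paths[0].layers)
        )
        u_target = u_pre - protocol.target * height
        segs = [
            Segment(
                "disp", u_pre, u_target, protocol.ramp_duration,
                n_steps=max(config.ramp_steps, 20),
            ),
            Segment("disp", u_target, u_target, protocol.hold_duration),
        ]
        hist = solver.simulate(segs, state=start_state)
        tt = hist.t - start_state.t
        vals = np.interp(times, tt, hist.force)
        meta["t_hold_start_s"] = protocol.ramp_duration
        meta["u_preload_mm"] = float(u_pre)
        meta["u_held_mm"] = float(u_target)
        meta["strain_reference_height_mm"] = float(height)
        ts = TimeSeries(t=times, value=vals, channel="reaction_force", metadata=meta)

    ts.metadata["final_state_u_mm"] = float(hist.final_state.u_top)
    ts.metadata["final_state_force_N"] = float(
        hist.final_state.reaction_force
        if hist.final_state.reaction_force
        else solver.reaction(hist.final_state)
    )
    ts.metadata["surrogate"] = "1D two-path confined column (no lateral bulging)"
    return ts


# ---------------------------------------------------------------------------
# analytic consolidation oracle


def terzaghi_reference(
    H: float,
    HA: float,
    k: float,
    load: float,
    times: np.ndarray,
    area: float = 1.0,
    drainage: str = "double",
    n_terms: int = 200,
) -> np.ndarray:
    """Classical one-dimensional consolidation settlement for a step load.

    Parameters are in solver units: H mm, HA MPa, k mm^4/(N s), load N,
    area mm^2.  Returns settlement (mm, positive down) at ``times``.
    """
    if drainage not in ("double", "single"):
        raise ValueError("drainage must be 'double' or 'single'")
    h = H / 2.0 if drainage == "double" else H
    cv = HA * k  # mm^2/s
    Tv = cv * np.asarray(times, dtype=float) / h**2
    m = np.arange(n_terms)
    M = (2 * m + 1) * math.pi / 2.0
    U = 1.0 - np.sum(
        (2.0 / M**2)[None, :] * np.exp(-(M**2)[None, :] * Tv[:, None]), axis=1
    )
    return (load / area) * H / HA * U
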