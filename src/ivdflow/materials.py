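"""Constitutive and transport laws for disc tissues.

The soft tissues (NP, AF, CEP) are biphasic swelling mixtures: a
Holmes-Mow hyperelastic solid matrix, Holmes-Mow deformation-dependent
hydraulic permeability, and a Donnan-equilibrium osmotic pressure driven by
the fixed charge density (FCD) of the glycosaminoglycans.  The bony
endplates are compressible neo-Hookean with constant permeability.
Collagen and elastic fibers follow a stretch-only toe-linear law.

Degeneration (severe grade) is represented by reduced NP/AF fixed charge
density and reduced cartilage-endplate permeability.

All stress laws here are specialized to the laterally confined kinematics
of the axial column (F = diag(lambda_z, 1, 1), so J = lambda_z), which is
what the reduced-order solver needs.  Units follow :mod:`ivdflow.units`:
MPa, mm, s; ``k0`` is kept in the tabulated 1e-4 mm^4/(N s) scale on the
card and converted by the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from . import units
from .population import lamella_interpolation

__all__ = [
    "MaterialCard",
    "FiberCard",
    "Environment",
    "TISSUES",
    "load_card",
    "load_fiber_card",
    "default_environment",
    "fcd_current",
    "donnan_pressure",
    "holmes_mow_permeability",
    "holmes_mow_axial_stress",
    "neo_hookean_axial_stress",
    "fiber_toe_linear_stress",
    "aggregate_modulus",
    "card_to_si",
    "card_from_si",
]

TISSUES = ("BEP", "CEP", "NP", "AF")
FIBER_REGIONS = ("AO", "AI", "PO", "PI", "NEF", "CEP-axial")


@dataclass(frozen=True)
class MaterialCard:
    """Per-tissue, per-condition constitutive and transport parameters."""

    tissue: str
    condition: str
    Em: float  # Young's modulus, MPa
    nu: float  # Poisson ratio
    beta_m: float  # Holmes-Mow solid/permeability exponent (0 for BEP)
    M: float  # permeability exponential coefficient (0 for BEP)
    k0: float  # initial permeability, tabulated units of 1e-4 mm^4/(N s)
    phi0w: float  # initial water volume fraction
    cf0: float  # initial fixed charge density, mmol/L (signed, <= 0)
    Phi: float = 1.0  # osmotic coefficient
    af_inner_outer: Optional[dict] = None  # raw (inner, outer) pairs for AF

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0w < 1.0:
            raise ValueError("phi0w must lie in (0, 1)")
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")
        if self.cf0 > 0:
            raise ValueError("cf0 is a negative (or zero) fixed charge density")

    @property
    def phi0s(self) -> float:
        """Initial solid volume fraction."""
        return 1.0 - self.phi0w

    @property
    def lame(self) -> tuple[float, float]:
        """(lambda, mu) Lame constants from (Em, nu), MPa."""
        lam = self.Em * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.Em / (2 * (1 + self.nu))
        return lam, mu

    @property
    def HA(self) -> float:
        """Aggregate (confined-compression) modulus, MPa."""
        return aggregate_modulus(self.Em, self.nu)

    @property
    def k0_mm(self) -> float:
        """Initial permeability in plain mm^4/(N s)."""
        return self.k0 * units.K0_TABLE_SCALE


@dataclass(frozen=True)
class FiberCard:
    """Toe-linear fiber family parameters for one AF region, the elastic
    fiber family, or the simplified (directional-moduli) CEP model."""

    region: str
    Ef: float  # fiber modulus, MPa
    beta_f: float  # rate of fiber stiffening
    I0: float  # critical stretch square; toe/linear junction
    sf_II: float = 1.0  # elastic-fiber family scale factor
    Ef_ap: Optional[float] = None  # CEP anterior-posterior modulus, MPa
    Ef_l: Optional[float] = None  # CEP lateral modulus, MPa
    Ef_a: Optional[float] = None  # CEP axial modulus, MPa

    def __post_init__(self) -> None:
        if self.Ef < 0:
            raise ValueError("Ef must be >= 0")
        if self.I0 < 1.0:
            raise ValueError("I0 must be >= 1")
        if self.beta_f <= 0:
            raise ValueError("beta_f must be > 0")


@dataclass(frozen=True)
class Environment:
    """External bath: 0.15 M saline at room temperature by default."""

    c0: float = 150.0  # mmol/L
    T: float = 298.15  # K
    R: float = units.R_GAS  # J/(mol K)

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.T <= 0:
            raise ValueError("bath concentration and temperature must be > 0")


def _raw_tables() -> dict:
    with resources.files("ivdflow.data").joinpath("materials.yaml").open() as fh:
        return yaml.safe_load(fh)


_TABLES = _raw_tables()


def default_environment() -> Environment:
    env = _TABLES["environment"]
    return Environment(c0=env["c0"], T=env["T"], R=env["R"])


def load_card(
    tissue: str,
    condition: str,
    lamella_fraction: Optional[float] = None,
    overrides: Optional[dict] = None,
) -> MaterialCard:
    """Material card for a tissue/condition; AF cards require the radial
    lamella station so the inner->outer gradients can be evaluated."""
    if tissue not in TISSUES:
        raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    if condition not in ("healthy", "degenerated"):
        raise KeyError(f"unknown condition {condition!r}")
    raw = dict(_TABLES["tissues"][tissue][condition])
    if overrides:
        raw.update(overrides)

    af_pairs = None
    if tissue == "AF":
        if lamella_fraction is None:
            raise ValueError("AF cards require a lamella_fraction in [0, 1]")
        af_pairs = {key: tuple(raw[key]) for key in ("k0", "phi0w", "cf0")}
        for key, (inner, outer) in af_pairs.items():
            raw[key] = lamella_interpolation(lamella_fraction, inner, outer)
    elif lamella_fraction is not None:
        raise ValueError(f"lamella_fraction only applies to AF, not {tissue}")

    return MaterialCard(
        tissue=tissue,
        condition=condition,
        Em=raw["Em"],
        nu=raw["nu"],
        beta_m=raw["beta_m"] if raw["beta_m"] is not None else 0.0,
        M=raw["M"] if raw["M"] is not None else 0.0,
        k0=raw["k0"],
        phi0w=raw["phi0w"],
        cf0=raw["cf0"],
        Phi=raw.get("Phi", 1.0),
        af_inner_outer=af_pairs,
    )


def load_fiber_card(region: str) -> FiberCard:
    if region not in FIBER_REGIONS:
        raise KeyError(f"unknown fiber region {region!r}; expected one of {FIBER_REGIONS}")
    raw = _TABLES["fibers"][region]
    return FiberCard(
        region=region,
        Ef=raw["Ef"],
        beta_f=raw["beta_f"],
        I0=raw["I0"],
        sf_II=raw.get("sf_II", 1.0),
        Ef_ap=raw.get("Ef_ap"),
        Ef_l=raw.get("Ef_l"),
        Ef_a=raw.get("Ef_a"),
    )


def aggregate_modulus(Em: float, nu: float) -> float:
    """Confined-compression small-strain modulus HA = E(1-nu)/((1+nu)(1-2nu))."""
    return Em * (1 - nu) / ((1 + nu) * (1 - 2 * nu))


# ---------------------------------------------------------------------------
# osmotic pressure

def fcd_current(cf0: float, phi0w: float, J) -> np.ndarray | float:
    """Fixed charge density in the deformed state.

    The charge is bound to the solid matrix, so dilution follows the fluid
    volume: |cF(J)| = |cf0| * phi0w / (J - 1 + phi0w).  Signed like cf0.
    """
    J = np.asarray(J, dtype=float)
    denom = J - 1.0 + phi0w
    if np.any(denom <= 0):
        raise ValueError("J <= 1 - phi0w: tissue compacted past its solid volume")
    out = cf0 * phi0w / denom
    return out if out.ndim else float(out)


def donnan_pressure(cF, env: Environment, Phi: float = 1.0) -> np.ndarray | float:
    """Ideal Donnan osmotic pressure difference against the bath, MPa.

    Delta-pi = Phi * R * T * (sqrt(cF^2 + 4 c0^2) - 2 c0), with
    concentrations in mol/m^3 (numerically mmol/L) and ideal activity
    coefficients.
    """
    cF = np.asarray(cF, dtype=float)
    c0 = units.concentration_to_si(env.c0)
    c = units.concentration_to_si(cF)
    dpi_pa = Phi * env.R * env.T * (np.sqrt(c**2 + 4 * c0**2) - 2 * c0)
    out = units.pressure_from_si(dpi_pa)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# transport

def holmes_mow_permeability(J, card: MaterialCard) -> np.ndarray | float:
    """Strain-dependent permeability k(J) = k0 ((J - phi0s)/(1 - phi0s))^beta_m
    * exp(M (J^2 - 1)/2), in the card's k0 units."""
    J = np.asarray(J, dtype=float)
    phi0s = card.phi0s
    if np.any(J <= phi0s):
        raise ValueError("J <= 1 - phi0w: permeability undefined past compaction")
    out = card.k0 * ((J - phi0s) / (1 - phi0s)) ** card.beta_m * np.exp(card.M * (J**2 - 1) / 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# solid stress laws (laterally confined uniaxial kinematics, J = lambda_z)

def holmes_mow_axial_stress(lambda_z, card: MaterialCard) -> np.ndarray | float:
    """Axial Cauchy stress of the Holmes-Mow solid under confined uniaxial
    stretch, MPa.

    For F = diag(lz, 1, 1) the standard Holmes-Mow strain energy with
    exponent beta_m and Lame constants from (Em, nu) reduces to

        sigma_zz = HA (lz^2 - 1) / (2 lz) * lz^(-2 beta_m)
                   * exp(beta_m (lz^2 - 1)),

    which vanishes at lz = 1 and has small-strain slope HA.
    """
    lz = np.asarray(lambda_z, dtype=float)
    if np.any(lz <= card.phi0s):
        raise ValueError("stretch past the compaction limit")
    b = card.beta_m
    out = card.HA * (lz**2 - 1) / (2 * lz) * np.exp(b * ((lz**2 - 1) - 2 * np.log(lz)))
    return out if out.ndim else float(out)


def neo_hookean_axial_stress(lambda_z, Em: float, nu: float) -> np.ndarray | float:
    """Axial Cauchy stress of a compressible neo-Hookean solid under
    confined uniaxial stretch, MPa (used for the bony endplates)."""
    lz = np.asarray(lambda_z, dtype=float)
    lam = Em * nu / ((1 + nu) * (1 - 2 * nu))
    mu = Em / (2 * (1 + nu))
    out = mu * (lz**2 - 1) / lz + lam * np.log(lz) / lz
    return out if out.ndim else float(out)


def fiber_toe_linear_stress(lambda_f, card: FiberCard) -> np.ndarray | float:
    """Stretch-only toe-linear fiber stress, MPa.

    Zero in compression (lambda_f^2 <= 1); a power-law toe with exponent
    beta_f up to the critical stretch square I0; linear with modulus Ef
    beyond, with stress and tangent continuous at the junction.  Scaled by
    sf_II for elastic-fiber families.
    """
    scalar = np.isscalar(lambda_f) or np.ndim(lambda_f) == 0
    lf = np.atleast_1d(np.asarray(lambda_f, dtype=float))
    out = np.zeros_like(lf)
    I = lf**2
    sqI0 = math.sqrt(card.I0)

    if card.I0 > 1.0:
        # tangent continuity fixes the toe coefficient:
        #   c * beta_f * (I0-1)^(beta_f-1) * 2 sqrt(I0) = Ef
        c = card.Ef / (2 * card.beta_f * sqI0 * (card.I0 - 1) ** (card.beta_f - 1))
        sigma_junction = c * (card.I0 - 1) ** card.beta_f
        toe = (I > 1.0) & (I <= card.I0)
        out[toe] = c * (I[toe] - 1.0) ** card.beta_f
    else:
        sigma_junction = 0.0
        toe = np.zeros_like(I, dtype=bool)

    lin = I > card.I0
    out[lin] = sigma_junction + card.Ef * (lf[lin] - sqI0)
    out *= card.sf_II
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# SI round-trip helpers

def card_to_si(card: MaterialCard) -> MaterialCard:
    """Express a card in strict SI (Pa, m^4/(N s), mol/m^3)."""
    return replace(
        card,
        Em=units.pressure_to_si(card.Em),
        k0=units.permeability_to_si(card.k0 * units.K0_TABLE_SCALE),
        cf0=units.concentration_to_si(card.cf0),
        af_inner_outer=None,
    )


def card_from_si(card: MaterialCard) -> MaterialCard:
    """Inverse of :func:`card_to_si`; reproduces tabulated values exactly."""
    return replace(
        card,
        Em=units.pressure_from_si(card.Em),
        k0=units.permeability_from_si(card.k0) / units.K0_TABLE_SCALE,
        cf0=units.concentration_from_si(card.cf0),
    )
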