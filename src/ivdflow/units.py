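"""Unit conventions and conversion helpers.

The package computes internally in a self-consistent millimetre system:
length mm, force N, stress MPa, time s, permeability mm^4/(N s),
concentration mmol/L (== mol/m^3).  This is the unit system the material
tables are printed in, up to the 1e-4 scale on the tabulated permeability
column, so values round-trip exactly.  Converters to strict SI are provided
for interoperability.
"""

from __future__ import annotations

#: multiply a tabulated k0 (printed in units of 1e-4 mm^4/(N s)) to get mm^4/(N s)
K0_TABLE_SCALE = 1e-4

#: gas constant, J/(mol K)
R_GAS = 8.314

MPA_TO_PA = 1e6
MM_TO_M = 1e-3
#: mm^4/(N s) -> m^4/(N s)
PERM_MM_TO_SI = 1e-12
#: mmol/L -> mol/m^3 (numerically identical)
MMOL_PER_L_TO_MOL_PER_M3 = 1.0


def pressure_to_si(p_mpa: float) -> float:
    return p_mpa * MPA_TO_PA


def pressure_from_si(p_pa: float) -> float:
    return p_pa / MPA_TO_PA


def permeability_to_si(k_mm: float) -> float:
    """mm^4/(N s) -> m^4/(N s)."""
    return k_mm * PERM_MM_TO_SI


def permeability_from_si(k_si: float) -> float:
    return k_si / PERM_MM_TO_SI


def concentration_to_si(c_mmol_per_l: float) -> float:
    """mmol/L -> mol/m^3 (identity in magnitude)."""
    return c_mmol_per_l * MMOL_PER_L_TO_MOL_PER_M3


def concentration_from_si(c_mol_per_m3: float) -> float:
    return c_mol_per_m3 / MMOL_PER_L_TO_MOL_PER_M3
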