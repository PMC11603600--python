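"""Ideal-gas statistical thermodynamics of species records.

Partition functions are per molecule; the translational one is evaluated at
the molecular volume k_B T / P, which makes ``S = R(ln q + T dlnq/dT + 1)``
reproduce the Sackur-Tetrode equation.  Vibrational partition functions are
bottom-of-well referenced, so ZPE lives inside q_vib and the hindered-rotor
substitution q_HO -> q_HR is a clean per-mode drop-in.

Rotational symmetry numbers are *excluded* from the partition functions by
default (``include_sigma=False``); reaction symmetry enters the rate constant
once, through the symmetry factor sigma_Rx = prod(sigma_R) / sigma_TS.

Standard-state bookkeeping (1 atm vs 1 M) follows the ideal-gas relation
K_c = K_p (V_m c^o)^{-dn}: for a bimolecular activation (dn = -1)
``dG(1M) = dG(1atm) + dn RT ln(V_m c^o)`` (1.894 kcal/mol lower at
298.15 K); unimolecular dG is standard-state independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .constants import (AMU, ANGSTROM, ATM, C_LIGHT, H, HARTREE_KCALMOL, K_B,
                        N_A, R_J, R_KCAL, R_CAL, C_STANDARD, molar_volume_L)
from .errors import ValidationError
from .hindered_rotor import vibrational_thermo
from .records import SpeciesRecord

__all__ = [
    "ThermoConditions", "PartitionBreakdown", "ThermoState", "ActivationThermo",
    "q_translational", "q_rotational", "q_vibrational_HO", "q_electronic",
    "thermo_from_Q", "activation_thermo",
]


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature (K) and pressure (atm); molar volume follows ideal-gas law."""

    T: float
    P: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValidationError("temperature must be > 0 K")
        if self.P <= 0:
            raise ValidationError("pressure must be > 0 atm")

    @property
    def V_m(self) -> float:
        """Molar volume, L mol^-1."""
        return molar_volume_L(self.T, self.P)


@dataclass
class PartitionBreakdown:
    """Component partition functions and their constant-volume dln q/dT."""

    q_trans: float
    q_rot: float
    q_vib: float
    q_elec: float
    dlnq_dT: float   # total, K^-1 (constant-V)

    @property
    def total(self) -> float:
        return self.q_trans * self.q_rot * self.q_vib * self.q_elec


@dataclass
class ThermoState:
    """Molar state functions at (T, standard state).  Energies kcal mol^-1,
    entropy cal mol^-1 K^-1.  U/H/G include the electronic energy."""

    T: float
    ZPE: float
    U: float
    H: float
    S: float
    G: float
    standard_state: str
    breakdown: PartitionBreakdown | None = None


@dataclass
class ActivationThermo:
    """Generalized Gibbs activation energy with standard-state bookkeeping."""

    T: float
    dG_1atm: float    # kcal mol^-1
    dG_1M: float      # kcal mol^-1
    dn: int           # 0 unimolecular, -1 bimolecular


# ----------------------------------------------------------------------------
# component partition functions
# ----------------------------------------------------------------------------

def q_translational(mass_amu: float, T: float, V_m3: float) -> float:
    """(2 pi m k_B T / h^2)^{3/2} V for one molecule in volume V (m^3)."""
    if mass_amu <= 0:
        raise ValidationError("mass must be positive")
    m = mass_amu * AMU
    return (2.0 * math.pi * m * K_B * T / H**2) ** 1.5 * V_m3


def q_rotational(record: SpeciesRecord, T: float, include_sigma: bool = False) -> float:
    """Rigid-rotor rotational partition function from the record's geometry.

    Linear: 8 pi^2 I k T / (sigma h^2); nonlinear:
    sqrt(pi)/sigma * prod_i (8 pi^2 I_i k T / h^2)^{1/2}.  A single atom has
    no rotation (returns 1 with a warning).  With ``include_sigma=False`` the
    symmetry number is omitted (it enters once, via the reaction symmetry
    factor).
    """
    if record.n_atoms < 2:
        warnings.warn(f"species {record.label!r} is a single atom; q_rot = 1",
                      stacklevel=2)
        return 1.0
    sigma = record.rot_symmetry_number if include_sigma else 1
    moments = record.principal_moments_amu_A2() * AMU * ANGSTROM**2   # kg m^2
    if record.is_linear:
        I = moments[-1]   # the two nonzero moments are equal for a linear top
        return 8.0 * math.pi**2 * I * K_B * T / (sigma * H**2)
    if moments[0] <= 0 or moments[0] < 1e-10 * moments[-1]:
        raise ValidationError(
            f"species {record.label!r} claimed nonlinear but has a ~zero "
            "principal moment of inertia")
    prod = 1.0
    for I in moments:
        prod *= math.sqrt(8.0 * math.pi**2 * I * K_B * T / H**2)
    return math.sqrt(math.pi) / sigma * prod


def q_vibrational_HO(frequencies_cm, T: float) -> float:
    """Product of bottom-of-well harmonic-oscillator partition functions."""
    q = 1.0
    for i, f in enumerate(frequencies_cm):
        if f <= 0:
            raise ValidationError(f"mode {i} has non-positive frequency {f}")
        u = H * C_LIGHT * f / (K_B * T)
        q *= math.exp(-0.5 * u) / (1.0 - math.exp(-u))
    return q


def q_electronic(levels, T: float) -> float:
    """Sum over electronic levels: sum_i g_i exp(-eps_i / k_B T), eps in cm^-1."""
    return sum(g * math.exp(-H * C_LIGHT * e / (K_B * T)) for g, e in levels)


# ----------------------------------------------------------------------------
# full-molecule thermodynamics
# ----------------------------------------------------------------------------

def thermo_from_Q(record: SpeciesRecord, cond: ThermoConditions,
                  include_sigma: bool = False, hr_model: str = "HO") -> ThermoState:
    """State functions of one ideal-gas species from its partition function.

    U = RT^2 dlnQ/dT|_V + N_A E_elec;  S = R(ln Q + T dlnQ/dT + 1);
    H = U + RT;  G = H - TS.  ``hr_model`` selects HO/PG/AS treatment of the
    record's torsions.
    """
    T = cond.T
    V_molec = K_B * T / (cond.P * ATM)             # m^3 per molecule

    q_t = q_translational(record.total_mass_amu, T, V_molec)
    dln_t = 1.5 / T                                # constant-V derivative

    if record.n_atoms >= 2:
        q_r = q_rotational(record, T, include_sigma)
        dln_r = (1.0 / T) if record.is_linear else (1.5 / T)
    else:
        q_r, dln_r = 1.0, 0.0

    lnq_v, U_v, S_v = vibrational_thermo(record, T, hr_model)
    dln_v = U_v / (R_KCAL * T**2)                  # U = RT^2 dlnq/dT

    q_e = q_electronic(record.multiplicity_levels, T)
    # <eps> per molecule, J
    mean_eps = sum(g * (H * C_LIGHT * e) * math.exp(-H * C_LIGHT * e / (K_B * T))
                   for g, e in record.multiplicity_levels) / q_e
    dln_e = mean_eps / (K_B * T**2)

    dlnQ = dln_t + dln_r + dln_v + dln_e
    lnQ = math.log(q_t) + math.log(q_r) + lnq_v + math.log(q_e)

    E_elec = record.electronic_energy * HARTREE_KCALMOL        # kcal/mol
    U = R_KCAL * T**2 * dlnQ + E_elec
    S = R_CAL * (lnQ + T * dlnQ + 1.0)                          # cal/mol/K
    H_ = U + R_KCAL * T
    G = H_ - T * S / 1000.0
    state = "1 atm" if abs(cond.P - 1.0) < 1e-12 else f"{cond.P} atm"
    breakdown = PartitionBreakdown(q_trans=q_t, q_rot=q_r,
                                   q_vib=math.exp(lnq_v), q_elec=q_e,
                                   dlnq_dT=dlnQ)
    return ThermoState(T=T, ZPE=record.zpe_kcal(), U=U, H=H_, S=S, G=G,
                       standard_state=state, breakdown=breakdown)


def activation_thermo(reactants: list[SpeciesRecord], gts: SpeciesRecord,
                      cond: ThermoConditions, hr_model: str = "HO") -> ActivationThermo:
    """Generalized Gibbs activation energy at 1 atm and 1 M.

    dG(1atm) = G_GTS - sum_i G_Ri with sigma-free partition functions and the
    species' electronic energies included; dG(1M) applies the K_c/K_p
    standard-state shift for the reaction molecularity.
    """
    if not 1 <= len(reactants) <= 2:
        raise ValidationError(
            f"unsupported molecularity: {len(reactants)} reactants (1 or 2 allowed)")
    mass_R = sum(r.total_mass_amu for r in reactants)
    charge_R = sum(r.charge for r in reactants)
    if abs(mass_R - gts.total_mass_amu) > 0.5:
        warnings.warn("reactant and transition-structure masses do not balance",
                      stacklevel=2)
    if charge_R != gts.charge:
        warnings.warn("reactant and transition-structure charges do not balance",
                      stacklevel=2)
    G_gts = thermo_from_Q(gts, cond, include_sigma=False, hr_model=hr_model).G
    G_R = sum(thermo_from_Q(r, cond, include_sigma=False, hr_model=hr_model).G
              for r in reactants)
    dG_1atm = G_gts - G_R
    dn = 0 if len(reactants) == 1 else -1
    # K_c = K_p (c^o R T / P^o)^{-dn}  =>  dG(1M) = dG(P) + dn RT ln(V_m c^o);
    # for dn = -1 the 1 M value is lower by RT ln(24.465) = 1.894 kcal/mol at
    # 298.15 K, which is what makes bimolecular rate constants larger in the
    # concentration standard state.  dG(1M) is pressure-invariant.
    shift = dn * R_KCAL * cond.T * math.log(cond.V_m * C_STANDARD)
    return ActivationThermo(T=cond.T, dG_1atm=dG_1atm, dG_1M=dG_1atm + shift, dn=dn)
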