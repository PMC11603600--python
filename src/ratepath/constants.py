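"""Physical constants and unit conversions (CODATA 2018, exact SI where defined).

Every module imports its constants from here; no physical constant is
hard-coded anywhere else.  Values for the defined SI constants (h, k_B, N_A, c)
are exact; derived conversion factors are carried at full double precision.
"""

from __future__ import annotations

# --- defined SI constants (exact, CODATA 2018 / 2019 SI redefinition) ---
K_B = 1.380649e-23            # Boltzmann constant, J K^-1
H = 6.62607015e-34            # Planck constant, J s
N_A = 6.02214076e23           # Avogadro constant, mol^-1
C_LIGHT = 2.99792458e10       # speed of light, cm s^-1 (spectroscopy units)
HBAR = H / (2.0 * 3.141592653589793)

# --- gas constant, two views ---
R_J = K_B * N_A               # 8.31446261815324 J mol^-1 K^-1
CAL = 4.184                   # thermochemical calorie, J (exact)
R_CAL = R_J / CAL             # cal mol^-1 K^-1
R_KCAL = R_CAL / 1000.0       # kcal mol^-1 K^-1

# --- measured constants (CODATA 2018) ---
AMU = 1.66053906660e-27       # atomic mass unit, kg
HARTREE_J = 4.3597447222071e-18   # hartree, J

# --- unit conversions ---
ANGSTROM = 1.0e-10            # m
BOHR = 0.529177210903e-10     # m (CODATA 2018 Bohr radius)
ATM = 101325.0                # Pa (exact)
HARTREE_KCALMOL = HARTREE_J * N_A / (CAL * 1000.0)   # 627.5094740631 kcal mol^-1
WAVENUMBER_J = H * C_LIGHT    # energy of 1 cm^-1, J
WAVENUMBER_KCALMOL = WAVENUMBER_J * N_A / (CAL * 1000.0)
KCALMOL_J = CAL * 1000.0 / N_A    # 1 kcal mol^-1 in J per molecule

# --- standard states ---
P_STANDARD_ATM = 1.0          # atm
C_STANDARD = 1.0              # mol L^-1

CONSTANTS_VERSION = "CODATA-2018"


def molar_volume_L(T: float, P_atm: float = P_STANDARD_ATM) -> float:
    """Ideal-gas molar volume in L mol^-1 at T (K) and P (atm)."""
    return R_J * T / (P_atm * ATM) * 1000.0


def constants_table() -> str:
    """Human-readable dump of the authoritative constants table (for audit)."""
    rows = [
        ("k_B / J K^-1", K_B),
        ("h / J s", H),
        ("N_A / mol^-1", N_A),
        ("c / cm s^-1", C_LIGHT),
        ("R / J mol^-1 K^-1", R_J),
        ("R / cal mol^-1 K^-1", R_CAL),
        ("amu / kg", AMU),
        ("hartree / J", HARTREE_J),
        ("hartree / kcal mol^-1", HARTREE_KCALMOL),
        ("bohr / m", BOHR),
        ("1 cm^-1 / J", WAVENUMBER_J),
        ("1 atm / Pa", ATM),
    ]
    lines = [f"# constants table ({CONSTANTS_VERSION})"]
    lines += [f"{name}\t{value:.15g}" for name, value in rows]
    return "\n".join(lines) + "\n"
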