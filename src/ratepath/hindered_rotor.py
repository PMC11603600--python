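"""One-dimensional hindered-rotor partition functions and thermodynamics.

A torsion (internal rotation) with potential ``V(phi) = V0/2 * (1 - cos(M*phi))``
is treated by two classic interpolation schemes:

* **Pitzer-Gwinn (PG)** - the classical hindered-rotor partition function
  ``q_class = q_FR * exp(-y/2) * I0(y/2)`` (``y = V0/RT``) multiplied by the
  quantum/classical harmonic-oscillator ratio ``q_HO/q_CHO`` evaluated at the
  torsional frequency.
* **Ayala-Schlegel (AS)** - PG times a rational correction
  ``(1 + P2*exp(-y/2)) / (1 + P1*exp(-y/2))`` where P1 and P2 are fifth-order
  polynomials in ``x = 1/q_FR`` and ``y``.  The coefficients shipped in
  ``data/as_poly.json`` were fitted against the exact eigenvalue sum of the
  torsional Hamiltonian (see :func:`torsion_oracle`) over the domain recorded
  in that file.

Thermodynamic properties (U, S, H, G) are available in closed form for every
component (free rotor, classical HO, quantum HO, classical hindered rotor,
and the PG/AS totals); each closed form is cross-checked against numerical
T-differentiation of ln q in the test suite.

All per-mode partition functions are bottom-of-well referenced, so zero-point
energy emerges from q itself and a hindered rotor can replace a harmonic mode
as a clean drop-in factor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import eigvals_banded
from scipy.special import i0e, i1e

from .constants import (AMU, ANGSTROM, C_LIGHT, H, HBAR, K_B, KCALMOL_J, N_A,
                        R_KCAL, R_CAL)
from .errors import NumericalError, ValidationError
from .records import SpeciesRecord, TorsionSpec

__all__ = [
    "HRResult", "barrier_from_frequency", "resolve_barrier", "q_free_rotor",
    "q_harmonic", "q_classical_harmonic", "q_pitzer_gwinn", "hr_thermo_pg",
    "q_ayala_schlegel", "hr_thermo_as", "compose_vibrational",
    "vibrational_thermo", "torsion_oracle",
]


# ----------------------------------------------------------------------------
# elementary pieces
# ----------------------------------------------------------------------------

def barrier_from_frequency(spec: TorsionSpec) -> float:
    """Torsional barrier V0 (kcal mol^-1) from the harmonic relation.

    For the well ``V = V0/2 (1 - cos(M*phi))`` the curvature at the minimum
    fixes the harmonic frequency, giving ``V0 = 8 pi^2 c^2 nu^2 I_r / M^2``
    per molecule (times N_A per mole).
    """
    if spec.n_minima == 0:
        raise ValidationError("M = 0 has no defined barrier")
    I_r = spec.reduced_moment_amu_A2 * AMU * ANGSTROM**2          # kg m^2
    v0_J = 8.0 * math.pi**2 * C_LIGHT**2 * spec.freq_cm**2 * I_r / spec.n_minima**2
    return v0_J / KCALMOL_J


def resolve_barrier(spec: TorsionSpec) -> float:
    """Return the barrier to use: a user/scan value wins over the harmonic one.

    A scan-derived barrier and the frequency-derived one can legitimately
    differ; a disagreement beyond a factor of 2 is flagged as suspicious.
    """
    harmonic = barrier_from_frequency(spec)
    if spec.barrier_kcal is None:
        return harmonic
    v0 = spec.barrier_kcal
    if v0 > 0 and harmonic > 0:
        ratio = max(v0 / harmonic, harmonic / v0)
        if ratio > 2.0:
            warnings.warn(
                f"supplied torsional barrier {v0:.3g} kcal/mol disagrees with the "
                f"frequency-derived value {harmonic:.3g} kcal/mol by more than 2x",
                stacklevel=2)
    return v0


def q_free_rotor(spec: TorsionSpec, T: float) -> float:
    """Classical free-rotor partition function (8 pi^3 I_r k T)^1/2 / (sigma h)."""
    I_r = spec.reduced_moment_amu_A2 * AMU * ANGSTROM**2
    return math.sqrt(8.0 * math.pi**3 * I_r * K_B * T) / (spec.symmetry_number * H)


def q_harmonic(freq_cm: float, T: float) -> float:
    """Bottom-of-well quantum HO partition function exp(-u/2)/(1-exp(-u))."""
    u = H * C_LIGHT * freq_cm / (K_B * T)
    return math.exp(-0.5 * u) / (1.0 - math.exp(-u))


def q_classical_harmonic(freq_cm: float, T: float) -> float:
    """Classical HO partition function k_B T / (h c nu)."""
    return K_B * T / (H * C_LIGHT * freq_cm)


# ----------------------------------------------------------------------------
# result container
# ----------------------------------------------------------------------------

@dataclass
class HRResult:
    """Partition functions and thermodynamic contributions of one torsion.

    U, H, G in kcal mol^-1; S in cal mol^-1 K^-1.  ``rows`` holds the
    per-component breakdown (free_rotor / classical_ho / quantum_ho /
    classical / total), each a dict with keys U, S, H, G.
    """

    model: str
    T: float
    x: float
    y: float
    q_FR: float
    q_CHO: float
    q_HO: float
    q_class: float
    q_PG: float
    q_AS: float | None
    U: float
    S: float
    H: float
    G: float
    rows: dict = field(default_factory=dict)

    @property
    def q(self) -> float:
        return self.q_AS if self.model == "AS" else self.q_PG


def _component_rows(spec: TorsionSpec, T: float, v0: float):
    """PG component thermodynamics; returns (qs, rows) dicts."""
    RT = R_KCAL * T
    y = v0 / RT
    u = H * C_LIGHT * spec.freq_cm / (K_B * T)

    qFR = q_free_rotor(spec, T)
    qCHO = q_classical_harmonic(spec.freq_cm, T)
    qHO = q_harmonic(spec.freq_cm, T)
    # classical hindered rotor; i0e(z) = exp(-z) I0(z) keeps large y finite
    qclass = qFR * i0e(0.5 * y)
    bessel_ratio = i1e(0.5 * y) / i0e(0.5 * y)    # I1/I0 in [0, 1)

    def mk(U, lnq):
        S = R_CAL * lnq + 1000.0 * U / T          # cal/mol/K
        return {"U": U, "S": S, "H": U, "G": -R_KCAL * T * lnq}

    rows = {
        "free_rotor": mk(0.5 * RT, math.log(qFR)),
        "classical_ho": mk(RT, math.log(qCHO)),
        "quantum_ho": mk(RT * u * (0.5 + 1.0 / math.expm1(u)), math.log(qHO)),
        "classical": mk(RT * (0.5 + 0.5 * y * (1.0 - bessel_ratio)),
                        math.log(qclass)),
    }
    total = {k: rows["classical"][k] + rows["quantum_ho"][k] - rows["classical_ho"][k]
             for k in ("U", "S", "H", "G")}
    rows["total"] = total
    qs = {"q_FR": qFR, "q_CHO": qCHO, "q_HO": qHO, "q_class": qclass,
          "q_PG": qclass * qHO / qCHO, "x": 1.0 / qFR, "y": y}
    return qs, rows


# ----------------------------------------------------------------------------
# Pitzer-Gwinn
# ----------------------------------------------------------------------------

def q_pitzer_gwinn(spec: TorsionSpec, T: float) -> HRResult:
    """Pitzer-Gwinn hindered-rotor result (partition function + properties)."""
    v0 = resolve_barrier(spec)
    qs, rows = _component_rows(spec, T, v0)
    t = rows["total"]
    return HRResult(model="PG", T=T, x=qs["x"], y=qs["y"], q_FR=qs["q_FR"],
                    q_CHO=qs["q_CHO"], q_HO=qs["q_HO"], q_class=qs["q_class"],
                    q_PG=qs["q_PG"], q_AS=None,
                    U=t["U"], S=t["S"], H=t["H"], G=t["G"], rows=rows)


def hr_thermo_pg(spec: TorsionSpec, T: float) -> HRResult:
    """Alias of :func:`q_pitzer_gwinn`; the result carries the full property table."""
    return q_pitzer_gwinn(spec, T)


# ----------------------------------------------------------------------------
# Ayala-Schlegel
# ----------------------------------------------------------------------------

_AS_DATA: dict | None = None


def _as_data() -> dict:
    global _AS_DATA
    if _AS_DATA is None:
        with resources.files("ratepath.data").joinpath("as_poly.json").open() as fh:
            raw = json.load(fh)
        for key in ("P1", "P2"):
            raw[key] = {
                "exponents": np.array(raw[key]["exponents"], dtype=int),
                "coeffs": np.array(raw[key]["coeffs"], dtype=float),
            }
        _AS_DATA = raw
    return _AS_DATA


def _poly_eval(poly: dict, x: float, y: float):
    """Evaluate P, dP/dx, dP/dy for one fitted polynomial."""
    ex = poly["exponents"]
    c = poly["coeffs"]
    xi, yj = ex[:, 0], ex[:, 1]
    xpow = x ** xi
    ypow = y ** yj
    P = float(np.sum(c * xpow * ypow))
    with np.errstate(divide="ignore", invalid="ignore"):
        dPdx = float(np.sum(np.where(xi > 0, c * xi * x ** np.maximum(xi - 1, 0) * ypow, 0.0)))
        dPdy = float(np.sum(np.where(yj > 0, c * yj * xpow * y ** np.maximum(yj - 1, 0), 0.0)))
    return P, dPdx, dPdy


def _as_correction(x: float, y: float, T: float):
    """AS correction factor C and d(ln C)/dT at fixed spec (x ~ T^-1/2, y ~ T^-1)."""
    data = _as_data()
    dom = data["domain"]
    xc, yc = x, y
    if not (dom["x"][0] * 0.0 <= x <= dom["x"][1]) or y > dom["y"][1]:
        warnings.warn(
            f"(x={x:.3g}, y={y:.3g}) outside the Ayala-Schlegel fit domain "
            f"x<={dom['x'][1]}, y<={dom['y'][1]}; clamping", stacklevel=3)
        xc = min(x, dom["x"][1])
        yc = min(y, dom["y"][1])
    E = math.exp(-0.5 * yc)
    P1, dP1dx, dP1dy = _poly_eval(data["P1"], xc, yc)
    P2, dP2dx, dP2dy = _poly_eval(data["P2"], xc, yc)
    den1 = 1.0 + P1 * E
    den2 = 1.0 + P2 * E
    if den1 <= 0 or den2 <= 0:
        raise NumericalError("Ayala-Schlegel correction denominator non-positive")
    C = den2 / den1
    # T-dependence through x(T) and y(T): dx/dT = -x/2T, dy/dT = -y/T,
    # dE/dT = E*y/(2T).  Clamped values move with the same rates (the clamp is
    # a plateau only outside the physical domain of the fit).
    dxdT = -0.5 * xc / T
    dydT = -yc / T
    dEdT = E * yc / (2.0 * T)

    def dln(P, dPdx, dPdy, den):
        dPdT = dPdx * dxdT + dPdy * dydT
        return (E * dPdT + P * dEdT) / den

    dlnCdT = dln(P2, dP2dx, dP2dy, den2) - dln(P1, dP1dx, dP1dy, den1)
    return C, dlnCdT


def q_ayala_schlegel(spec: TorsionSpec, T: float) -> HRResult:
    """Ayala-Schlegel hindered-rotor result: PG times the fitted correction."""
    res = q_pitzer_gwinn(spec, T)
    C, dlnCdT = _as_correction(res.x, res.y, T)
    q_AS = res.q_PG * C
    RT = R_KCAL * T
    dU = R_KCAL * T**2 * dlnCdT                  # kcal/mol
    U = res.U + dU
    G = res.G - RT * math.log(C)
    S = 1000.0 * (U - G) / T                      # cal/mol/K; identity G = H - TS
    rows = dict(res.rows)
    rows["total"] = {"U": U, "S": S, "H": U, "G": G}
    return HRResult(model="AS", T=T, x=res.x, y=res.y, q_FR=res.q_FR,
                    q_CHO=res.q_CHO, q_HO=res.q_HO, q_class=res.q_class,
                    q_PG=res.q_PG, q_AS=q_AS, U=U, S=S, H=U, G=G, rows=rows)


def hr_thermo_as(spec: TorsionSpec, T: float) -> HRResult:
    """Alias of :func:`q_ayala_schlegel` (full property table included)."""
    return q_ayala_schlegel(spec, T)


_MODELS = {"HO": None, "PG": q_pitzer_gwinn, "AS": q_ayala_schlegel}


# ----------------------------------------------------------------------------
# mode composition
# ----------------------------------------------------------------------------

def _torsion_mode_indices(record: SpeciesRecord) -> list[int]:
    """Resolve which harmonic mode each torsion replaces.

    Explicit ``mode_index`` wins; otherwise the unique real mode matching the
    torsional frequency within 1 cm^-1 is used.
    """
    indices: list[int] = []
    for t in record.torsions:
        if t.mode_index is not None:
            idx = t.mode_index
        else:
            cands = [i for i, f in enumerate(record.frequencies)
                     if f > 0 and abs(f - t.freq_cm) <= 1.0]
            if len(cands) != 1:
                raise ValidationError(
                    f"cannot match torsion (nu={t.freq_cm} cm^-1) to a unique "
                    f"harmonic mode; found {len(cands)} candidates — set mode_index")
            idx = cands[0]
        if record.frequencies[idx] < 0:
            raise ValidationError("torsion mode points at the imaginary mode")
        if idx in indices:
            raise ValidationError("two torsions claim the same harmonic mode")
        indices.append(idx)
    return indices


def compose_vibrational(record: SpeciesRecord, T: float, model: str = "HO") -> float:
    """Total vibrational partition function with torsions under the given model.

    ``q_vib = prod(nontorsional q_HO) * prod(torsional q_HR)``; with
    ``model='HO'`` every real mode is harmonic (torsions revert to their
    harmonic modes).  Imaginary modes never contribute.
    """
    lnq, _, _ = vibrational_thermo(record, T, model)
    return math.exp(lnq)


def vibrational_thermo(record: SpeciesRecord, T: float, model: str = "HO"):
    """(ln q_vib, U_kcal, S_cal) of the vibrational manifold.

    Bottom-of-well referenced, so U includes the ZPE.
    """
    if model not in _MODELS:
        raise ValidationError(f"unknown hindered-rotor model {model!r}")
    torsion_idx = set(_torsion_mode_indices(record)) if model != "HO" else set()
    lnq = 0.0
    U = 0.0   # kcal/mol
    S = 0.0   # cal/mol/K
    for i, f in enumerate(record.frequencies):
        if f < 0 or i in torsion_idx:
            continue
        if f == 0:
            raise ValidationError(f"mode {i} has zero frequency")
        u = H * C_LIGHT * f / (K_B * T)
        lnq_i = -0.5 * u - math.log(1.0 - math.exp(-u))
        U_i = R_KCAL * T * u * (0.5 + 1.0 / math.expm1(u))
        lnq += lnq_i
        U += U_i
        S += R_CAL * lnq_i + 1000.0 * U_i / T
    if model != "HO":
        fn = _MODELS[model]
        for t in record.torsions:
            res = fn(t, T)
            lnq += math.log(res.q)
            U += res.U
            S += res.S
    return lnq, U, S


# ----------------------------------------------------------------------------
# exact eigenvalue oracle
# ----------------------------------------------------------------------------

def torsion_oracle(spec: TorsionSpec, T: float, n_grid: int = 2048,
                   check_convergence: bool = False) -> float:
    """Exact 1-D torsional partition function by eigenvalue summation.

    Solves ``H = -(hbar^2/2 I_r) d^2/dphi^2 + (V0/2)(1 - cos(M phi))`` in a
    periodic plane-wave basis of ``n_grid`` functions (the cosine potential is
    banded there, so the solve is spectral-accurate and cheap), references
    energies to the potential minimum, Boltzmann-sums, and divides by the
    torsional symmetry number.  Validation oracle only - not a production
    method.
    """
    if n_grid < 512:
        raise ValidationError("n_grid must be >= 512 for a converged oracle")
    q = _oracle_sum(spec, T, n_grid)
    if check_convergence:
        q2 = _oracle_sum(spec, T, 2 * n_grid)
        if abs(q2 - q) > 1e-8 * abs(q2):
            raise NumericalError(
                f"torsion oracle not converged: n={n_grid} gives {q}, "
                f"n={2*n_grid} gives {q2}")
    return q


def _oracle_sum(spec: TorsionSpec, T: float, n_grid: int) -> float:
    I_r = spec.reduced_moment_amu_A2 * AMU * ANGSTROM**2
    B = HBAR**2 / (2.0 * I_r)                      # J
    v0 = resolve_barrier(spec) * KCALMOL_J         # J per molecule
    M = spec.n_minima
    K = n_grid // 2
    m = np.arange(-K, K + 1)
    n = m.size
    diag = B * m.astype(float)**2 + 0.5 * v0
    bands = np.zeros((M + 1, n))
    bands[0] = diag
    if v0 > 0:
        bands[M, : n - M] = -0.25 * v0             # <m|cos(M phi)|m +/- M>
    energies = eigvals_banded(bands, lower=True)
    # V has its minimum at 0 by construction, so eigenvalues are already
    # referenced to the potential minimum
    beta = 1.0 / (K_B * T)
    return float(np.exp(-beta * energies).sum()) / spec.symmetry_number
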