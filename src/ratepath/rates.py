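"""TST, generalized-TST, and CVT rate constants; Eckart tunneling; branching.

The thermodynamic formulation is used throughout:

    k_GT(s, T) = sigma_Rx * (k_B T / h) * (c^o)^{dn} * exp(-dG_GT(s)/RT)

with sigma-free partition functions inside dG and the reaction symmetry
applied once as sigma_Rx = prod(sigma_R) / sigma_TS (sigma_GTS is taken
independent of s, equal to sigma_TS).  The CVT rate constant is the discrete
minimum of k_GT over the computed generalized transition states plus the
saddle point - equivalently, the maximum of dG_GT over the same candidate
set - so k_CVT <= k_TST holds by construction.

Unimolecular rates are s^-1; bimolecular rates are reported in
cm^3 molecule^-1 s^-1 (the 1 M-standard-state M^-1 s^-1 value times
10^3 / N_A).

Tunneling uses the one-dimensional asymmetric Eckart barrier fitted to the
ZPE-corrected forward/reverse barrier heights and the saddle-point imaginary
frequency, with the transmission probability Boltzmann-averaged by adaptive
quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.integrate import quad

from .constants import C_LIGHT, H, K_B, KCALMOL_J, N_A, R_KCAL
from .errors import NumericalError, ValidationError
from .records import SpeciesRecord
from .statthermo import ThermoConditions, activation_thermo

__all__ = [
    "ReactionSystem", "RateResult", "EckartBarrier", "symmetry_factor",
    "k_tst", "k_gt", "k_cvt", "eckart_kappa", "eckart_barrier_from_system",
    "overall_rate", "branching_ratios", "recrossing_factor", "compute_rates",
]


@dataclass
class ReactionSystem:
    """One elementary reaction: reactants, saddle point, and GTS series."""

    reactants: list[SpeciesRecord]
    ts: SpeciesRecord
    gts_series: list[SpeciesRecord] = field(default_factory=list)
    products: list[SpeciesRecord] = field(default_factory=list)
    complexes: list[SpeciesRecord] = field(default_factory=list)
    sigma_rx_override: Fraction | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2:
            raise ValidationError("molecularity must be 1 or 2")
        if self.ts.n_imaginary != 1:
            raise ValidationError("TS must have exactly one imaginary frequency")
        svals = [g.s_value for g in self.gts_series]
        if any(v is None for v in svals):
            raise ValidationError("every GTS record needs an s_value")
        if len(set(svals)) != len(svals):
            raise ValidationError("GTS s_values must be distinct")
        if any(abs(v) < 1e-12 for v in svals):
            raise ValidationError("GTS s_values must exclude s = 0 (that is the TS)")

    @property
    def molecularity(self) -> int:
        return len(self.reactants)


@dataclass
class RateResult:
    """Rate constants over a temperature grid for one reaction pathway.

    Units: s^-1 (unimolecular) or cm^3 molecule^-1 s^-1 (bimolecular).
    """

    label: str
    temperatures: np.ndarray
    molecularity: int
    k_tst: np.ndarray
    k_cvt: np.ndarray | None = None
    s_cvt_star: np.ndarray | None = None
    kappa_eckart: np.ndarray | None = None
    dG_1M: np.ndarray | None = None          # kcal/mol, at the saddle point
    k_gt_curves: list[np.ndarray] | None = None   # per T: (n_points, 2) [s, k]
    sigma_rx: Fraction = Fraction(1)
    branching_percent: np.ndarray | None = None

    @property
    def unit(self) -> str:
        return "s^-1" if self.molecularity == 1 else "cm^3 molecule^-1 s^-1"

    @property
    def recrossing(self) -> np.ndarray | None:
        if self.k_cvt is None:
            return None
        return self.k_tst / self.k_cvt


# ----------------------------------------------------------------------------
# symmetry and elementary rate expressions
# ----------------------------------------------------------------------------

def symmetry_factor(system: ReactionSystem) -> Fraction:
    """sigma_Rx = prod(sigma_i^R) / sigma_TS, constant along s.

    An explicit override (the RXSYM input keyword) wins over the records.
    """
    if system.sigma_rx_override is not None:
        return Fraction(system.sigma_rx_override)
    if system.ts.rot_symmetry_number == 0:
        raise ValidationError("sigma_TS must be nonzero")
    num = 1
    for r in system.reactants:
        num *= r.rot_symmetry_number
    return Fraction(num, system.ts.rot_symmetry_number)


def _k_from_dG(dG_1M: float, T: float, molecularity: int, sigma_rx: Fraction) -> float:
    """Thermodynamic-formulation rate constant from dG++(1M) in kcal/mol."""
    k = float(sigma_rx) * (K_B * T / H) * math.exp(-dG_1M / (R_KCAL * T))
    if molecularity == 2:
        k *= 1000.0 / N_A        # M^-1 s^-1  ->  cm^3 molecule^-1 s^-1
    return k


def k_tst(system: ReactionSystem, T: float, hr_model: str = "HO") -> float:
    """Conventional TST rate constant (dividing surface at the saddle point)."""
    cond = ThermoConditions(T=T)
    act = activation_thermo(system.reactants, system.ts, cond, hr_model=hr_model)
    return _k_from_dG(act.dG_1M, T, system.molecularity, symmetry_factor(system))


def k_gt(system: ReactionSystem, s: float, T: float, hr_model: str = "HO") -> float:
    """Generalized-TST rate constant with the dividing surface at coordinate s."""
    if abs(s) < 1e-12:
        return k_tst(system, T, hr_model)
    matches = [g for g in system.gts_series if abs(g.s_value - s) < 1e-9]
    if not matches:
        raise ValidationError(f"no generalized-TS record at s = {s}")
    cond = ThermoConditions(T=T)
    act = activation_thermo(system.reactants, matches[0], cond, hr_model=hr_model)
    return _k_from_dG(act.dG_1M, T, system.molecularity, symmetry_factor(system))


def k_cvt(system: ReactionSystem, T: float, hr_model: str = "HO"):
    """(k_CVT, s*) - the discrete minimum of k_GT over {GTS series + saddle}.

    Ties are broken toward s = 0, then toward the reactant side.
    """
    candidates = [(0.0, k_tst(system, T, hr_model))]
    candidates += [(g.s_value, k_gt(system, g.s_value, T, hr_model))
                   for g in system.gts_series]
    k_min = min(k for _, k in candidates)
    tied = [s for s, k in candidates if k <= k_min * (1.0 + 1e-14)]
    s_star = min(tied, key=lambda s: (abs(s), s))
    return k_min, s_star


# ----------------------------------------------------------------------------
# Eckart tunneling
# ----------------------------------------------------------------------------

@dataclass
class EckartBarrier:
    """Asymmetric Eckart barrier: ZPE-corrected heights (kcal/mol) and the
    magnitude of the saddle-point imaginary frequency (cm^-1)."""

    forward_barrier: float
    reverse_barrier: float
    imaginary_frequency: float

    def __post_init__(self) -> None:
        if self.forward_barrier <= 0 or self.reverse_barrier <= 0:
            raise ValidationError("Eckart barrier heights must be positive")
        if self.imaginary_frequency < 0:
            raise ValidationError("imaginary frequency magnitude must be >= 0")


def eckart_barrier_from_system(system: ReactionSystem) -> EckartBarrier:
    """Build the Eckart barrier from saddle-point and asymptote data.

    Forward barrier: E0(TS) - E0(reactants); reverse: E0(TS) - E0(products),
    both ZPE-corrected.  Requires product records.
    """
    if not system.products:
        raise ValidationError("Eckart barrier needs product records")

    def e0(records):
        from .constants import HARTREE_KCALMOL
        return sum(r.electronic_energy * HARTREE_KCALMOL + r.zpe_kcal()
                   for r in records)

    ts0 = e0([system.ts])
    dv1 = ts0 - e0(system.reactants)
    dv2 = ts0 - e0(system.products)
    return EckartBarrier(forward_barrier=dv1, reverse_barrier=dv2,
                         imaginary_frequency=system.ts.imaginary_frequency)


def _eckart_transmission(E: float, alpha1: float, alpha2: float) -> float:
    """Transmission probability through the asymmetric Eckart barrier.

    E is in units of the forward barrier height (xi = E/V1);
    alpha_i = 2 pi V_i / (h nu*).  Standard dimensionless formulation.
    """
    xi = E
    if xi <= 0:
        return 0.0
    inv = 1.0 / math.sqrt(alpha1) + 1.0 / math.sqrt(alpha2)
    two_pi_a = 2.0 * math.sqrt(alpha1 * xi) / inv
    arg_b = alpha1 * (xi - 1.0) + alpha2
    if arg_b <= 0.0:
        return 0.0        # product channel closed
    two_pi_b = 2.0 * math.sqrt(arg_b) / inv
    d_sq = alpha1 * alpha2 - math.pi**2 / 4.0
    # P = [cosh(a+b) - cosh(a-b)] / [cosh(a+b) + cosh(d)]; evaluate in logs
    # to stay finite for large arguments
    apb, amb = two_pi_a + two_pi_b, two_pi_a - two_pi_b
    two_pi_d = 2.0 * math.sqrt(d_sq) if d_sq > 0 else 0.0
    log_num = _log_cosh_diff(apb, amb)
    log_den = _log_cosh_sum(apb, two_pi_d) if d_sq > 0 else \
        _log_cosh_plus_cos(apb, 2.0 * math.sqrt(-d_sq))
    return math.exp(log_num - log_den)


def _log_cosh(z: float) -> float:
    z = abs(z)
    return z - math.log(2.0) + math.log1p(math.exp(-2.0 * z))


def _log_cosh_diff(a: float, b: float) -> float:
    """log(cosh a - cosh b) for a >= |b|."""
    if a <= abs(b):
        return -math.inf
    la, lb = _log_cosh(a), _log_cosh(b)
    return la + math.log1p(-math.exp(lb - la))


def _log_cosh_sum(a: float, b: float) -> float:
    la, lb = _log_cosh(a), _log_cosh(b)
    hi, lo = max(la, lb), min(la, lb)
    return hi + math.log1p(math.exp(lo - hi))


def _log_cosh_plus_cos(a: float, b: float) -> float:
    """log(cosh a + cos b): d^2 < 0 branch (very thin barriers)."""
    val = math.cosh(a) if a < 700 else None
    if val is not None:
        return math.log(val + math.cos(b))
    return _log_cosh(a)   # cos term negligible


def eckart_kappa(barrier: EckartBarrier, T: float) -> float:
    """Boltzmann-averaged Eckart transmission coefficient kappa(T).

    kappa = integral_0^inf P(E) exp(-(E - V1)/k_B T) d(E/k_B T); the energy
    zero is the reactant asymptote.  kappa -> 1 as the imaginary frequency
    -> 0 (classical limit) and kappa >= 1 for real barriers.
    """
    if barrier.imaginary_frequency == 0:
        return 1.0
    v1 = barrier.forward_barrier * KCALMOL_J     # J per molecule
    v2 = barrier.reverse_barrier * KCALMOL_J
    h_nu = H * C_LIGHT * barrier.imaginary_frequency
    alpha1 = 2.0 * math.pi * v1 / h_nu
    alpha2 = 2.0 * math.pi * v2 / h_nu
    kT = K_B * T
    beta_v1 = v1 / kT

    def integrand(eps: float) -> float:
        # eps = E / kT measured from the reactant asymptote
        return _eckart_transmission(eps * kT / v1, alpha1, alpha2) * math.exp(-eps)

    upper = beta_v1 + 40.0
    val, err = quad(integrand, 0.0, upper, epsrel=1e-8, epsabs=0.0, limit=500,
                    points=[beta_v1] if beta_v1 < upper else None)
    if not math.isfinite(val) or (val > 0 and err / val > 1e-5):
        raise NumericalError(
            f"Eckart Boltzmann integral did not converge (value {val}, err {err})")
    return math.exp(beta_v1) * val


# ----------------------------------------------------------------------------
# pathway combination
# ----------------------------------------------------------------------------

def _pathway_rates(paths: list[RateResult], T: float, which: str) -> list[float]:
    mols = {p.molecularity for p in paths}
    if len(mols) != 1:
        raise ValidationError("cannot combine pathways of mixed molecularity/units")
    out = []
    for p in paths:
        i = int(np.argmin(np.abs(p.temperatures - T)))
        if abs(p.temperatures[i] - T) > 1e-6:
            raise ValidationError(f"pathway {p.label!r} has no entry at T = {T}")
        arr = p.k_cvt if (which == "cvt" and p.k_cvt is not None) else p.k_tst
        out.append(float(arr[i]))
    return out


def overall_rate(paths: list[RateResult], T: float, which: str = "cvt") -> float:
    """k_overall(T) = sum over parallel pathways of k_path(T)."""
    return sum(_pathway_rates(paths, T, which))


def branching_ratios(paths: list[RateResult], T: float, which: str = "cvt") -> list[float]:
    """Gamma_i = 100 * k_i / sum_j k_j, in percent."""
    ks = _pathway_rates(paths, T, which)
    total = sum(ks)
    if total <= 0:
        raise ValidationError("all pathway rate constants are zero")
    return [100.0 * k / total for k in ks]


def recrossing_factor(result: RateResult, T: float) -> float:
    """k_TST / k_CVT at T - the magnitude of the variational effect (>= 1)."""
    if result.k_cvt is None:
        raise ValidationError("CVT rates not computed for this result")
    i = int(np.argmin(np.abs(result.temperatures - T)))
    return float(result.k_tst[i] / result.k_cvt[i])


# ----------------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------------

def compute_rates(system: ReactionSystem, temperatures, method: str = "CVT",
                  hr_model: str = "HO", tunneling: bool = False,
                  barrier: EckartBarrier | None = None,
                  label: str = "path") -> RateResult:
    """Full rate-constant table over a temperature grid.

    ``method``: 'TST' or 'CVT'.  With ``tunneling=True`` an Eckart barrier is
    required (built from products if not supplied); the transmission
    coefficient is computed at the saddle point and composes multiplicatively
    with both k_TST and k_CVT.
    """
    temps = np.asarray(temperatures, dtype=float)
    if temps.size == 0 or np.any(temps <= 0) or np.any(np.diff(temps) <= 0):
        raise ValidationError("temperature grid must be positive and strictly increasing")
    method = method.upper()
    if method not in ("TST", "CVT"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "CVT" and not system.gts_series:
        raise ValidationError("CVT requires a nonempty series of generalized-TS records")

    sigma = symmetry_factor(system)
    ks_tst = np.array([k_tst(system, T, hr_model) for T in temps])
    dG = np.array([activation_thermo(system.reactants, system.ts,
                                     ThermoConditions(T=T), hr_model=hr_model).dG_1M
                   for T in temps])
    res = RateResult(label=label, temperatures=temps,
                     molecularity=system.molecularity, k_tst=ks_tst,
                     dG_1M=dG, sigma_rx=sigma)
    if method == "CVT":
        pairs = [k_cvt(system, T, hr_model) for T in temps]
        res.k_cvt = np.array([k for k, _ in pairs])
        res.s_cvt_star = np.array([s for _, s in pairs])
        res.k_gt_curves = []
        for T in temps:
            curve = [(0.0, k_tst(system, T, hr_model))]
            curve += [(g.s_value, k_gt(system, g.s_value, T, hr_model))
                      for g in system.gts_series]
            res.k_gt_curves.append(np.array(sorted(curve)))
    if tunneling:
        if barrier is None:
            barrier = eckart_barrier_from_system(system)
        res.kappa_eckart = np.array([eckart_kappa(barrier, T) for T in temps])
    return res
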