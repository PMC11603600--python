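"""Minimum-energy path, reaction force analysis, and TS-zone selection.

The reaction force F(s) = -dV/ds has a minimum (alpha, at s < 0) and a
maximum (gamma, at s > 0) at the inflection points of V(s).  These delimit
three zones along the path: reactant (A -> alpha), transition-state
(alpha -> gamma), and product (gamma -> B).  The TS zone holds the points
that matter for a variational rate-constant calculation; selecting only
those typically needs ~6-12% of the IRC points.

Differentiation uses a cubic spline through the (s, V) points (IRC data are
smooth and noise-free, so no smoothing is applied) with not-a-knot end
conditions, which keeps the derivative exact for cubic polynomials.  A
central-finite-difference mode is retained as a cross-check.

alpha and gamma are reported at grid points, never interpolated: a selected
point must be an actual IRC geometry for which a frequency job can be run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError

__all__ = ["MEPProfile", "RFAResult", "reaction_force", "locate_rfa_points",
           "select_ts_zone", "pcvt_fraction"]


@dataclass
class MEPProfile:
    """Ordered (s, V) path with the saddle point at s = 0.

    s in amu^1/2 bohr, V in kcal mol^-1 relative to the reactants.
    """

    s: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.s.size != self.V.size:
            raise ValidationError("s and V must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValidationError("s must be strictly increasing (duplicates forbidden)")

    @property
    def ts_index(self) -> int:
        idx = int(np.argmin(np.abs(self.s)))
        if abs(self.s[idx]) > 1e-9:
            raise ValidationError("profile does not contain the s = 0 point")
        return idx


@dataclass
class RFAResult:
    """Reaction-force critical points, zone assignment, and point economy."""

    alpha_s: float
    gamma_s: float
    force_curve: np.ndarray          # (n, 2): columns s, F
    zone_assignment: list[str]       # per point: 'reactant' | 'TS' | 'product'
    ts_zone_points: list[float] = field(default_factory=list)
    p_cvt_percent: float | None = None
    beta_s: float = 0.0


def reaction_force(profile: MEPProfile, scheme: str = "spline") -> np.ndarray:
    """F = -dV/ds at every input s.  Returns an (n, 2) array [s, F].

    ``scheme='spline'`` (default) differentiates a not-a-knot cubic spline;
    ``scheme='fd'`` uses second-order central differences (cross-check mode).
    """
    s, V = profile.s, profile.V
    if s.size < 7:
        raise ValidationError("need at least 7 path points to differentiate")
    if scheme == "spline":
        F = -CubicSpline(s, V).derivative()(s)
    elif scheme == "fd":
        F = -np.gradient(V, s, edge_order=2)
    else:
        raise ValidationError(f"unknown differentiation scheme {scheme!r}")
    return np.column_stack([s, F])


def locate_rfa_points(force: np.ndarray) -> RFAResult:
    """Locate alpha (min of F, s<0) and gamma (max of F, s>0) at grid points.

    Ties are broken toward s = 0 (keeps the TS zone tight).  A force curve
    with no interior extrema has no barrier structure and is rejected.
    """
    s, F = force[:, 0], force[:, 1]
    neg = s < 0
    pos = s > 0
    if not neg.any() or not pos.any():
        raise ValidationError("force curve must cover both signs of s")

    def _extremum(mask: np.ndarray, kind: str) -> float:
        vals = F[mask]
        ss = s[mask]
        target = vals.min() if kind == "min" else vals.max()
        cand = ss[np.isclose(vals, target, rtol=0, atol=0)]
        return cand[np.argmin(np.abs(cand))]   # tie-break: nearest s=0

    alpha = float(_extremum(neg, "min"))
    gamma = float(_extremum(pos, "max"))

    # a true barrier climbs on the reactant side (F < 0) and descends on the
    # product side (F > 0); a monotone force curve has no such structure
    F_a = float(F[s == alpha][0])
    F_g = float(F[s == gamma][0])
    if not (F_a < 0.0 < F_g):
        raise ValidationError("no barrier structure: reaction force is monotone")
    i_a = int(np.where(s == alpha)[0][0])
    i_g = int(np.where(s == gamma)[0][0])
    if i_a == 0 or i_g == s.size - 1:
        warnings.warn("one branch is truncated before F returns to ~0; "
                      "using the available extremum", stacklevel=2)

    zones = []
    for si in s:
        if si < alpha:
            zones.append("reactant")
        elif si <= gamma:
            zones.append("TS")
        else:
            zones.append("product")
    return RFAResult(alpha_s=alpha, gamma_s=gamma, force_curve=force,
                     zone_assignment=zones)


def select_ts_zone(profile: MEPProfile, rfa: RFAResult) -> list[float]:
    """All IRC points with alpha <= s <= gamma, excluding s = 0, ascending.

    The saddle point itself is excluded: its optimized structure is already
    required as the TS input, so no extra frequency job is needed there.
    """
    sel = [float(si) for si in profile.s
           if rfa.alpha_s <= si <= rfa.gamma_s and abs(si) > 1e-12]
    if not sel:
        raise ValidationError(
            "no nonstationary points fall inside the TS zone; "
            "recompute the IRC with a smaller step size")
    rfa.ts_zone_points = sel
    rfa.p_cvt_percent = pcvt_fraction(len(sel), profile.s.size - 1)
    return sel


def pcvt_fraction(n_zone: int, n_irc: int) -> float:
    """P_CVT(%) = 100 * (TS-zone points) / (IRC points), to one decimal."""
    if n_irc <= 0:
        raise ValidationError("IRC point count must be positive")
    if not 0 <= n_zone <= n_irc:
        raise ValidationError("need 0 <= n_zone <= n_irc")
    return round(100.0 * n_zone / n_irc, 1)
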