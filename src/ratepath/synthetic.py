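"""Fully synthetic, analytically characterized reaction fixtures.

Everything the other modules read can be generated here: species records,
vendor-dialect frequency logs, IRC profiles, generalized-TS series,
torsion cases, and complete on-disk run trees with a ``*.eif`` file.  The
potential along the path and the mode-frequency trajectories are analytic,
so every ground-truth quantity (reaction-force critical points, the
temperature-dependent position of the maximum generalized Gibbs activation
energy) is computable by brute force on the same grid, independently of the
production code.

These fixtures emulate the *shape* of real electronic-structure data (a
barrier with smooth wings, modes that stiffen or soften along the path);
they are not physically realistic potential-energy surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import C_LIGHT, H, HARTREE_KCALMOL, K_B, R_KCAL
from .errors import ValidationError
from .records import SpeciesRecord, TorsionSpec
from .chem_io import write_species_record, GEOMETRY_PLACEHOLDER
from .rates import ReactionSystem
from .chem_io import IRCTable

__all__ = ["SyntheticReactionSpec", "GroundTruth", "make_reaction",
           "make_zero_barrier_unimolecular", "make_torsion_case",
           "write_fixture_tree", "write_zero_barrier_tree", "write_qc_log"]


@dataclass
class SyntheticReactionSpec:
    """Parameters of one synthetic reaction (see module docstring).

    ``freq_shift_amp`` tilts the lowest ``n_shift_modes`` transition-structure
    frequencies along s as ``nu_i(s) = nu_i (1 + amp * tanh(s/width))``;
    a negative amplitude stiffens the reactant side and pulls the
    high-temperature Gibbs-energy maximum to s < 0 (an entropy-driven shift).
    """

    molecularity: int = 2
    barrier_kcal: float = 5.0
    delta_e_rxn_kcal: float = -8.0
    profile: str = "sech2"            # 'sech2' (symmetric) or 'eckart'
    width_L: float = 0.35             # amu^1/2 bohr
    n_side: int = 100
    step: float = 0.05                # amu^1/2 bohr
    imag_freq_cm: float = 1400.0
    freq_shift_amp: float = 0.0
    freq_shift_width: float = 0.5
    n_shift_modes: int = 3
    gts_halfwidth: float = 1.0        # emit GTS records for 0 < |s| <= this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.molecularity not in (1, 2):
            raise ValidationError("molecularity must be 1 or 2")
        if self.barrier_kcal <= 0:
            raise ValidationError("barrier must be positive (no interior maximum otherwise)")
        if self.profile not in ("sech2", "eckart"):
            raise ValidationError(f"unknown profile {self.profile!r}")
        if self.profile == "eckart":
            if self.barrier_kcal - self.delta_e_rxn_kcal <= 0:
                raise ValidationError("reverse barrier must be positive")
        if self.step <= 0 or self.width_L <= 0 or self.n_side < 10:
            raise ValidationError("path shape parameters invalid")


@dataclass
class GroundTruth:
    """Brute-force reference quantities for one synthetic reaction."""

    alpha_s_analytic: float
    gamma_s_analytic: float
    s_grid: np.ndarray
    V_kcal: np.ndarray
    s_star: dict = field(default_factory=dict)    # T -> grid argmax of dG_GT

    def dg_argmax(self, T: float) -> float:
        return self.s_star[T]


# ----------------------------------------------------------------------------
# analytic path shapes
# ----------------------------------------------------------------------------

def _potential_kcal(spec: SyntheticReactionSpec, s: np.ndarray) -> np.ndarray:
    if spec.profile == "sech2":
        return spec.barrier_kcal / np.cosh(s / spec.width_L) ** 2
    v1 = spec.barrier_kcal
    v2 = v1 - spec.delta_e_rxn_kcal
    A = v1 - v2
    B = (math.sqrt(v1) + math.sqrt(v2)) ** 2
    # shift the maximum to s = 0: y = y0 * exp(s/L) with y0 = (A+B)/(B-A)
    y0 = (A + B) / (B - A) if B != A else 1.0
    y = y0 * np.exp(np.asarray(s) / spec.width_L)
    V = A * y / (1 + y) + B * y / (1 + y) ** 2
    return V - float(A * y0 / (1 + y0) + B * y0 / (1 + y0) ** 2) + v1


def _mode_freqs(spec: SyntheticReactionSpec, base: np.ndarray, s: float) -> np.ndarray:
    out = base.astype(float).copy()
    if spec.freq_shift_amp != 0.0:
        n = min(spec.n_shift_modes, out.size)
        out[:n] *= 1.0 + spec.freq_shift_amp * math.tanh(s / spec.freq_shift_width)
    return out


def _brute_force_dg_rel(spec: SyntheticReactionSpec, base: np.ndarray,
                        s: float, V_kcal: float, T: float) -> float:
    """s-dependent part of dG_GT(s, T), by direct summation (oracle).

    Only V(s) and the vibrational manifold vary along the path (geometry,
    mass and electronic levels are held fixed), so the argmax of
    ``V(s) - RT sum_i ln q_HO(nu_i(s))`` is the argmax of dG_GT.
    """
    g = V_kcal
    for nu in _mode_freqs(spec, base, s):
        u = H * C_LIGHT * nu / (K_B * T)
        lnq = -0.5 * u - math.log(1.0 - math.exp(-u))
        g -= R_KCAL * T * lnq
    return g


# ----------------------------------------------------------------------------
# species construction
# ----------------------------------------------------------------------------

_E_R1 = -76.40        # hartree, arbitrary but fixed reference energies
_E_R2 = -75.73

_TS_BASE_FREQS = np.array([310.0, 450.0, 620.0, 900.0, 1250.0, 1680.0,
                           3500.0, 3720.0])


def _reactant_records(spec: SyntheticReactionSpec, rng) -> list[SpeciesRecord]:
    r1 = SpeciesRecord(
        label="R1", role="R1",
        atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
               ("H", 1.00783, 0.9572, 0.0, 0.0),
               ("H", 1.00783, -0.2400, 0.9266, 0.0)],
        electronic_energy=_E_R1,
        frequencies=[1594.8, 3656.7, 3755.8],
        rot_symmetry_number=2)
    if spec.molecularity == 1:
        return [r1]
    r2 = SpeciesRecord(
        label="R2", role="R2",
        atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
               ("H", 1.00783, 0.9697, 0.0, 0.0)],
        electronic_energy=_E_R2,
        frequencies=[3738.0],
        multiplicity_levels=[(2, 0.0)],
        is_linear=True,
        rot_symmetry_number=1)
    return [r1, r2]


def _transition_record(spec: SyntheticReactionSpec, reactants, jitter,
                       s: float | None, V_kcal: float) -> SpeciesRecord:
    atoms = []
    offset = 0.0
    for r in reactants:
        for el, m, x, y, z in r.atoms:
            atoms.append((el, m, x + offset, y + 0.15 * offset, z))
        offset += 2.4
    # one shared deterministic jitter makes the structure nonplanar while
    # keeping the geometry identical at every path point
    atoms = [(el, m, x + dx, y + dy, z + dz)
             for (el, m, x, y, z), (dx, dy, dz) in zip(atoms, jitter)]
    e_r = sum(r.electronic_energy for r in reactants)
    energy = e_r + V_kcal / HARTREE_KCALMOL
    mult = [(2, 0.0)] if spec.molecularity == 2 else [(1, 0.0)]
    base = _TS_BASE_FREQS[: max(3, 3 * len(atoms) - 7)]
    if s is None:
        freqs = [-spec.imag_freq_cm] + list(base)
        role = "TS"
        s_val = None
    else:
        freqs = list(_mode_freqs(spec, base, s))
        role = "GTS"
        s_val = s
    return SpeciesRecord(label=f"{role}{'' if s is None else f'_{s:+.3f}'}",
                         role=role, atoms=atoms, electronic_energy=energy,
                         frequencies=freqs, multiplicity_levels=mult,
                         rot_symmetry_number=1, s_value=s_val)


def _product_records(spec: SyntheticReactionSpec, reactants) -> list[SpeciesRecord]:
    e_r = sum(r.electronic_energy for r in reactants)
    e_p = e_r + spec.delta_e_rxn_kcal / HARTREE_KCALMOL
    if spec.molecularity == 1:
        return [SpeciesRecord(
            label="P1", role="P1",
            atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
                   ("H", 1.00783, 0.9572, 0.0, 0.0),
                   ("H", 1.00783, -0.2400, 0.9266, 0.0)],
            electronic_energy=e_p,
            frequencies=[1610.0, 3660.0, 3760.0],
            rot_symmetry_number=2)]
    e_p1 = e_p + 0.012
    p1 = SpeciesRecord(
        label="P1", role="P1",
        atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
               ("H", 1.00783, 0.9572, 0.0, 0.0),
               ("H", 1.00783, -0.2400, 0.9266, 0.0)],
        electronic_energy=e_p1,
        frequencies=[1610.0, 3660.0, 3760.0],
        rot_symmetry_number=2)
    p2 = SpeciesRecord(
        label="P2", role="P2",
        atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
               ("H", 1.00783, 0.9750, 0.0, 0.0)],
        electronic_energy=e_p - e_p1,
        frequencies=[3650.0],
        multiplicity_levels=[(2, 0.0)],
        is_linear=True,
        rot_symmetry_number=1)
    return [p1, p2]


# ----------------------------------------------------------------------------
# public generators
# ----------------------------------------------------------------------------

def make_reaction(spec: SyntheticReactionSpec,
                  temperatures=(298.15, 500.0, 1000.0)):
    """Build (ReactionSystem, IRCTable, GroundTruth) from a synthetic spec.

    The ground truth holds analytic reaction-force critical points and, for
    each requested temperature, the grid point maximizing the generalized
    Gibbs activation energy, computed by direct summation.
    """
    rng = np.random.default_rng(spec.seed)
    s_grid = np.arange(-spec.n_side, spec.n_side + 1) * spec.step
    V = _potential_kcal(spec, s_grid)
    if V.argmax() != spec.n_side:
        raise ValidationError("path shape has no interior maximum at s = 0")

    reactants = _reactant_records(spec, rng)
    n_ts_atoms = sum(r.n_atoms for r in reactants)
    jitter = rng.normal(scale=0.02, size=(n_ts_atoms, 3))
    ts = _transition_record(spec, reactants, jitter, None, spec.barrier_kcal)
    base = np.array(ts.real_frequencies)
    gts = []
    for i, s in enumerate(s_grid):
        if abs(s) < 1e-12 or abs(s) > spec.gts_halfwidth + 1e-12:
            continue
        gts.append(_transition_record(spec, reactants, jitter, float(s),
                                      float(V[i])))
    products = _product_records(spec, reactants)
    system = ReactionSystem(reactants=reactants, ts=ts, gts_series=gts,
                            products=products)

    irc = IRCTable(s=s_grid, V=V / HARTREE_KCALMOL, step_size=spec.step)

    if spec.profile == "sech2":
        alpha = -spec.width_L * math.atanh(1.0 / math.sqrt(3.0))
        gamma = -alpha
    else:
        alpha, gamma = _dense_inflections(spec)
    truth = GroundTruth(alpha_s_analytic=alpha, gamma_s_analytic=gamma,
                        s_grid=s_grid, V_kcal=V)
    cand = [(float(s_grid[i]), float(V[i])) for i in range(s_grid.size)
            if abs(s_grid[i]) < 1e-12 or abs(s_grid[i]) <= spec.gts_halfwidth]
    for T in temperatures:
        vals = [_brute_force_dg_rel(spec, base, s, v, T) for s, v in cand]
        truth.s_star[T] = cand[int(np.argmax(vals))][0]
    return system, irc, truth


def make_zero_barrier_unimolecular() -> ReactionSystem:
    """Degenerate unimolecular system with dG++ = 0 exactly.

    The transition structure equals the reactant (same energy, geometry and
    real modes) plus one imaginary mode, so k_TST = k_B T / h at every T.
    """
    r1 = SpeciesRecord(
        label="R1", role="R1",
        atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
               ("H", 1.00783, 0.9572, 0.0, 0.0),
               ("H", 1.00783, -0.2400, 0.9266, 0.0)],
        electronic_energy=-76.40,
        frequencies=[1594.8, 3656.7, 3755.8],
        rot_symmetry_number=1)
    ts = SpeciesRecord(
        label="TS", role="TS",
        atoms=list(r1.atoms),
        electronic_energy=r1.electronic_energy,
        frequencies=[-800.0] + list(r1.frequencies),
        rot_symmetry_number=1)
    return ReactionSystem(reactants=[r1], ts=ts)


def write_zero_barrier_tree(outdir, temperatures=(298.15,)) -> Path:
    """On-disk run tree for the degenerate zero-barrier unimolecular system.

    The resulting TST rate constant equals k_B T / h exactly, which makes the
    tree a self-checking end-to-end fixture.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system = make_zero_barrier_unimolecular()
    write_species_record(system.reactants[0], outdir / "react1.yaml")
    write_species_record(system.ts, outdir / "ts.yaml")
    eif_path = outdir / "run.eif"
    eif_path.write_text(
        "METHOD TST\nREACT1 react1.yaml\nTS ts.yaml\n"
        "TEMPERATURE " + " ".join(f"{t:g}" for t in temperatures) + "\n")
    return eif_path


def _dense_inflections(spec: SyntheticReactionSpec):
    """Brute-force alpha/gamma of the analytic profile on a dense grid."""
    s = np.linspace(-spec.n_side * spec.step, spec.n_side * spec.step, 200001)
    V = _potential_kcal(spec, s)
    F = -np.gradient(V, s)
    neg, pos = s < 0, s > 0
    return float(s[neg][F[neg].argmin()]), float(s[pos][F[pos].argmax()])


def make_torsion_case(V0_kcal: float, I_r_amu_A2: float, M: int,
                      sigma_tau: int | None = None,
                      T_grid=(200.0, 298.15, 500.0, 1000.0)):
    """TorsionSpec with the frequency implied by the barrier, plus an exact
    eigenvalue-oracle q(T) table."""
    from .hindered_rotor import torsion_oracle
    from .constants import AMU, ANGSTROM, KCALMOL_J
    if V0_kcal <= 0 or I_r_amu_A2 <= 0 or M < 1:
        raise ValidationError("torsion parameters must be positive")
    sigma_tau = M if sigma_tau is None else sigma_tau
    I_SI = I_r_amu_A2 * AMU * ANGSTROM**2
    nu = M / (2.0 * math.pi * C_LIGHT) * math.sqrt(V0_kcal * KCALMOL_J / (2.0 * I_SI))
    ts = TorsionSpec(freq_cm=nu, reduced_moment_amu_A2=I_r_amu_A2, n_minima=M,
                     symmetry_number=sigma_tau, barrier_kcal=V0_kcal)
    table = {T: torsion_oracle(ts, T) for T in T_grid}
    return ts, table


# ----------------------------------------------------------------------------
# vendor-dialect log writer and fixture trees
# ----------------------------------------------------------------------------

_Z = {"H": 1, "He": 2, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
      "Cl": 17, "Ar": 18, "Br": 35, "I": 53}


def write_qc_log(record: SpeciesRecord, path) -> Path:
    """Write a minimal vendor-dialect frequency log for a record.

    Contains exactly the blocks the adapter contract reads: charge and
    multiplicity, a standard-orientation table, an SCF energy, the harmonic
    frequency block, atomic masses, and the rotational symmetry number.
    """
    path = Path(path)
    mult = record.multiplicity_levels[0][0]
    dash = " " + "-" * 69
    lines = [
        " Entering synthetic frequency job.",
        f" Charge =  {record.charge} Multiplicity = {mult}",
        "                         Standard orientation:",
        dash,
        " Center     Atomic      Atomic             Coordinates (Angstroms)",
        dash,
    ]
    for i, (el, m, x, y, z) in enumerate(record.atoms, 1):
        z_num = _Z.get(el, 0)
        lines.append(f"    {i:>3d}        {z_num:>3d}           0      "
                     f"{x:12.6f}{y:12.6f}{z:12.6f}")
    lines.append(dash)
    lines.append(f" SCF Done:  E(synth) =  {record.electronic_energy:.9f}     A.U.")
    lines.append(" Harmonic frequencies (cm**-1), IR intensities ...")
    freqs = list(record.frequencies)
    for i in range(0, len(freqs), 3):
        chunk = freqs[i:i + 3]
        lines.append(" Frequencies --  " + "  ".join(f"{f:10.4f}" for f in chunk))
    for i, (el, m, *_xyz) in enumerate(record.atoms, 1):
        lines.append(f" Atom  {i} has atomic number  {_Z.get(el, 0)} and mass  {m:9.5f}")
    lines.append(f" Rotational symmetry number  {record.rot_symmetry_number}")
    lines.append(" Normal termination of synthetic job.")
    path.write_text("\n".join(lines) + "\n")
    return path


_DEFAULT_TEMPLATE = f"""%chk=pathpoint.chk
#p freq=(projected) synthetic/6-31G

frequency analysis at a selected path point

0 2
{GEOMETRY_PLACEHOLDER}

"""


def write_fixture_tree(outdir, spec: SyntheticReactionSpec,
                       method: str = "CVT", hindrot: str | None = None,
                       temperatures=(298.15,)) -> Path:
    """Write an on-disk tree mirroring a real run; returns the *.eif path.

    Layout: species records (YAML; the TS additionally as a vendor-dialect
    log), a signed IRC profile, a ``pathpoints/`` directory of generalized-TS
    records, a frequency-job template, and the run-control ``run.eif``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    system, irc, _truth = make_reaction(spec, temperatures=tuple(temperatures))

    for i, r in enumerate(system.reactants, 1):
        write_species_record(r, outdir / f"react{i}.yaml")
    for i, p in enumerate(system.products, 1):
        write_species_record(p, outdir / f"prod{i}.yaml")
    write_species_record(system.ts, outdir / "ts.yaml")
    write_qc_log(system.ts, outdir / "ts.log")

    irc_lines = [f"{s:+.6f}  {v:.12f}" for s, v in zip(irc.s, irc.V)]
    (outdir / "irc_path.dat").write_text("\n".join(irc_lines) + "\n")

    pp = outdir / "pathpoints"
    pp.mkdir(exist_ok=True)
    for g in system.gts_series:
        write_species_record(g, pp / f"gts_s{g.s_value:+.4f}.yaml")

    (outdir / "freq_template.inp").write_text(_DEFAULT_TEMPLATE)

    eif = [f"METHOD {method}"]
    eif.append("REACT1 react1.yaml")
    if spec.molecularity == 2:
        eif.append("REACT2 react2.yaml")
    eif.append("TS ts.yaml")
    for i in range(1, len(system.products) + 1):
        eif.append(f"PROD{i} prod{i}.yaml")
    eif += ["IRC irc_path.dat", "PATHPOINTS pathpoints",
            "PATHPOINTS_INP freq_template.inp"]
    if hindrot:
        eif.append(f"HINDROT {hindrot}")
    eif.append("TEMPERATURE " + " ".join(f"{t:g}" for t in temperatures))
    eif_path = outdir / "run.eif"
    eif_path.write_text("\n".join(eif) + "\n")
    return eif_path
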