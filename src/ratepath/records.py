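"""Core domain records: species data and torsion parameters.

A :class:`SpeciesRecord` carries everything statistical thermodynamics needs
about one chemical species: Cartesian geometry with per-atom masses, the
electronic energy, harmonic frequencies (imaginary modes stored as negative
wavenumbers, the vendor convention), electronic levels, the rotational
symmetry number, and any internal-rotation (torsion) parameters.

Roles follow the reaction bookkeeping of gas-phase kinetics: R1/R2 reactants,
TS the saddle point, RC/PC reactant/product complexes, P1/P2 products, and
GTS a generalized transition state at a nonstationary path point s != 0
(frequencies at a GTS are expected to come from a reaction-coordinate
projected analysis, hence zero imaginary modes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

ROLES = ("R1", "R2", "TS", "RC", "PC", "P1", "P2", "GTS")


@dataclass
class TorsionSpec:
    """Parameters of one internal rotation treated as a 1-D hindered rotor.

    Attributes
    ----------
    freq_cm : torsional harmonic frequency nu_tau in cm^-1 (> 0).
    reduced_moment_amu_A2 : reduced moment of inertia I_r in amu A^2.
    n_minima : number of minima M of the torsional potential over 0..2pi.
    symmetry_number : torsional symmetry number sigma_tau.
    barrier_kcal : torsional barrier V0 in kcal mol^-1, or None to derive it
        from (freq_cm, reduced_moment_amu_A2, n_minima) via the harmonic
        relation of the V0*(1 - cos(M*phi))/2 well.
    mode_index : index (into the species' frequency list) of the harmonic
        mode this torsion replaces, or None when used stand-alone.
    """

    freq_cm: float
    reduced_moment_amu_A2: float
    n_minima: int | None = None
    symmetry_number: int = 1
    barrier_kcal: float | None = None
    mode_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_minima is None:
            # symmetric-top torsions (e.g. -CH3) dominate: M defaults to sigma_tau
            self.n_minima = int(self.symmetry_number)
        if self.freq_cm <= 0:
            raise ValidationError("torsional frequency must be > 0")
        if self.reduced_moment_amu_A2 <= 0:
            raise ValidationError("reduced moment of inertia must be > 0")
        if self.n_minima < 1:
            raise ValidationError("number of torsional minima M must be >= 1")
        if self.symmetry_number < 1:
            raise ValidationError("torsional symmetry number must be >= 1")


@dataclass
class SpeciesRecord:
    """One species' electronic-structure payload (see module docstring)."""

    label: str
    role: str
    atoms: list[tuple[str, float, float, float, float]]  # (element, mass/amu, x, y, z /A)
    electronic_energy: float                 # hartree
    frequencies: list[float] = field(default_factory=list)   # cm^-1, imaginary < 0
    multiplicity_levels: list[tuple[int, float]] = field(
        default_factory=lambda: [(1, 0.0)])  # (degeneracy, energy / cm^-1)
    rot_symmetry_number: int = 1
    is_linear: bool = False
    charge: int = 0
    torsions: list[TorsionSpec] = field(default_factory=list)
    s_value: float | None = None             # amu^1/2 bohr, GTS only

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.atoms:
            raise ValidationError("species must contain at least one atom")
        for el, m, *_ in self.atoms:
            if m <= 0:
                raise ValidationError(f"atom {el!r} has non-positive mass {m}")
        degs = [g for g, e in self.multiplicity_levels]
        if not self.multiplicity_levels or min(degs) < 1:
            raise ValidationError("need at least one electronic level with degeneracy >= 1")
        if not any(abs(e) < 1e-12 for g, e in self.multiplicity_levels):
            raise ValidationError("ground electronic level must sit at 0 cm^-1")
        if self.rot_symmetry_number < 1:
            raise ValidationError("rotational symmetry number must be >= 1")
        n_imag = self.n_imaginary
        if self.role == "TS" and n_imag != 1:
            raise ValidationError(
                f"TS record must have exactly one imaginary frequency, found {n_imag}")
        if self.role == "GTS" and n_imag != 0:
            raise ValidationError(
                "GTS record must have zero imaginary frequencies "
                "(provide a reaction-coordinate projected frequency analysis)")
        for t in self.torsions:
            if t.mode_index is not None:
                if not (0 <= t.mode_index < len(self.frequencies)):
                    raise ValidationError(f"torsion mode_index {t.mode_index} out of range")
                if self.frequencies[t.mode_index] < 0:
                    raise ValidationError("torsion mode_index points at the imaginary mode")

    # -- derived quantities ----------------------------------------------
    @property
    def n_imaginary(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)

    @property
    def imaginary_frequency(self) -> float | None:
        """Magnitude (cm^-1) of the imaginary mode, if any."""
        imag = [abs(f) for f in self.frequencies if f < 0]
        return imag[0] if imag else None

    @property
    def real_frequencies(self) -> list[float]:
        return [f for f in self.frequencies if f > 0]

    @property
    def total_mass_amu(self) -> float:
        return sum(a[1] for a in self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) Cartesian coordinates in Angstrom."""
        return np.array([[x, y, z] for _, _, x, y, z in self.atoms], dtype=float)

    def masses_amu(self) -> np.ndarray:
        return np.array([m for _, m, *_ in self.atoms], dtype=float)

    def principal_moments_amu_A2(self) -> np.ndarray:
        """Principal moments of inertia (amu A^2), ascending."""
        m = self.masses_amu()
        r = self.coordinates()
        com = (m[:, None] * r).sum(axis=0) / m.sum()
        d = r - com
        x, y, z = d[:, 0], d[:, 1], d[:, 2]
        Ixx = (m * (y**2 + z**2)).sum()
        Iyy = (m * (x**2 + z**2)).sum()
        Izz = (m * (x**2 + y**2)).sum()
        Ixy = -(m * x * y).sum()
        Ixz = -(m * x * z).sum()
        Iyz = -(m * y * z).sum()
        tensor = np.array([[Ixx, Ixy, Ixz], [Ixy, Iyy, Iyz], [Ixz, Iyz, Izz]])
        return np.sort(np.linalg.eigvalsh(tensor))

    def zpe_kcal(self) -> float:
        """Harmonic zero-point energy (real modes only), kcal mol^-1."""
        from .constants import WAVENUMBER_KCALMOL
        return 0.5 * sum(self.real_frequencies) * WAVENUMBER_KCALMOL
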