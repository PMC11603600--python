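"""Reading and writing every external artifact.

Canonical inputs are *neutral species records*: a small documented YAML
schema (``schema: ratepath-species-1``) holding one species' geometry,
energy, frequencies, electronic levels, symmetry and torsions.  A
vendor-style quantum-chemistry log parser is provided as an adapter for the
frequency-job dialect written by :mod:`ratepath.synthetic` (and structured
like mainstream program output), so no quantum-chemistry package is ever
required.

Other artifacts: IRC profile tables (two-column s/V text), the ``*.eif``
key-value run-control dialect, frequency-job input emission for selected
path points, and the tab-separated rate table.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .constants import HARTREE_KCALMOL
from .errors import ParseError, SchemaError, ValidationError
from .records import ROLES, SpeciesRecord, TorsionSpec

logger = logging.getLogger("ratepath")

__all__ = [
    "EifConfig", "IRCTable", "read_species_record", "write_species_record",
    "parse_qc_log", "parse_eif", "read_irc", "emit_pathpoint_inputs",
    "write_rate_table", "read_rate_table",
]


# ----------------------------------------------------------------------------
# neutral species records (YAML schema ratepath-species-1)
# ----------------------------------------------------------------------------

_SPECIES_SCHEMA = "ratepath-species-1"
_MANDATORY = ("label", "role", "atoms", "electronic_energy_hartree")


def read_species_record(path) -> SpeciesRecord:
    """Read a neutral species record (YAML, schema ``ratepath-species-1``)."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: not a mapping")
    if data.get("schema") != _SPECIES_SCHEMA:
        raise SchemaError(f"{path}: missing or unknown 'schema' "
                          f"(expected {_SPECIES_SCHEMA!r})")
    for key in _MANDATORY:
        if key not in data:
            raise SchemaError(f"{path}: mandatory field {key!r} missing")
    torsions = [TorsionSpec(
        freq_cm=t["freq_cm"],
        reduced_moment_amu_A2=t["reduced_moment_amu_A2"],
        n_minima=t.get("n_minima"),
        symmetry_number=t.get("symmetry_number", 1),
        barrier_kcal=t.get("barrier_kcal"),
        mode_index=t.get("mode_index"),
    ) for t in data.get("torsions", [])]
    try:
        return SpeciesRecord(
            label=str(data["label"]),
            role=str(data["role"]),
            atoms=[(str(a[0]), float(a[1]), float(a[2]), float(a[3]), float(a[4]))
                   for a in data["atoms"]],
            electronic_energy=float(data["electronic_energy_hartree"]),
            frequencies=[float(f) for f in data.get("frequencies_cm", [])],
            multiplicity_levels=[(int(g), float(e)) for g, e in
                                 data.get("multiplicity_levels", [[1, 0.0]])],
            rot_symmetry_number=int(data.get("rot_symmetry_number", 1)),
            is_linear=bool(data.get("is_linear", False)),
            charge=int(data.get("charge", 0)),
            torsions=torsions,
            s_value=(None if data.get("s_value") is None else float(data["s_value"])),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_species_record(record: SpeciesRecord, path) -> Path:
    """Write a record in the neutral YAML schema (round-trips exactly)."""
    path = Path(path)
    data = {
        "schema": _SPECIES_SCHEMA,
        "label": record.label,
        "role": record.role,
        "charge": record.charge,
        "rot_symmetry_number": record.rot_symmetry_number,
        "is_linear": record.is_linear,
        "electronic_energy_hartree": float(record.electronic_energy),
        "multiplicity_levels": [[int(g), float(e)] for g, e in record.multiplicity_levels],
        "frequencies_cm": [float(f) for f in record.frequencies],
        "atoms": [[str(el), float(m), float(x), float(y), float(z)]
                  for el, m, x, y, z in record.atoms],
    }
    if record.s_value is not None:
        data["s_value"] = float(record.s_value)
    if record.torsions:
        data["torsions"] = [{
            "freq_cm": t.freq_cm,
            "reduced_moment_amu_A2": t.reduced_moment_amu_A2,
            "n_minima": t.n_minima,
            "symmetry_number": t.symmetry_number,
            **({"barrier_kcal": t.barrier_kcal} if t.barrier_kcal is not None else {}),
            **({"mode_index": t.mode_index} if t.mode_index is not None else {}),
        } for t in record.torsions]
    with path.open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


# ----------------------------------------------------------------------------
# vendor-log adapter (frequency-job dialect)
# ----------------------------------------------------------------------------

_RE_SCF = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_RE_FREQ = re.compile(r"Frequencies\s*--\s*(.+)")
_RE_SYM = re.compile(r"Rotational symmetry number\s+(\d+)")
_RE_MULT = re.compile(r"Charge\s*=\s*(-?\d+)\s+Multiplicity\s*=\s*(\d+)")
_RE_MASS = re.compile(r"Atom\s+\d+ has atomic number\s+\d+ and mass\s+(\d+\.\d+)")


def parse_qc_log(path, dialect: str = "gaussian") -> SpeciesRecord:
    """Parse a completed frequency-analysis log into a species record.

    Only the ``gaussian`` frequency-job dialect is supported.  When the log
    holds several frequency blocks, the last one wins (a warning is logged);
    a missing symmetry-number line defaults to sigma = 1 with a warning.
    """
    if dialect != "gaussian":
        raise ParseError(f"unsupported log dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    if "Normal termination" not in text:
        raise ParseError(
            f"{path}: truncated log (no normal-termination line; "
            f"read {len(text.encode())} bytes)")

    geoms = _parse_orientation_blocks(text, path)
    if not geoms:
        raise ParseError(f"{path}: no geometry block found")
    elements, coords = geoms[-1]

    masses = [float(m) for m in _RE_MASS.findall(text)]
    if len(masses) < len(elements):
        raise ParseError(f"{path}: atomic masses missing or incomplete")
    masses = masses[-len(elements):]

    scf = _RE_SCF.findall(text)
    if not scf:
        raise ParseError(f"{path}: no SCF energy found")

    blocks = text.split("Harmonic frequencies")
    if len(blocks) < 2:
        raise ParseError(f"{path}: no frequency analysis in log")
    if len(blocks) > 2:
        logger.warning("%s: multiple frequency blocks; the last one wins", path)
    freqs = [float(v) for line in _RE_FREQ.findall(blocks[-1])
             for v in line.split()]

    msym = _RE_SYM.search(text)
    if msym:
        sigma = int(msym.group(1))
    else:
        sigma = 1
        logger.warning("%s: no rotational-symmetry-number line; defaulting sigma=1", path)

    mm = _RE_MULT.search(text)
    charge, mult = (int(mm.group(1)), int(mm.group(2))) if mm else (0, 1)

    n_imag = sum(1 for f in freqs if f < 0)
    role = "TS" if n_imag == 1 else "R1"
    return SpeciesRecord(
        label=path.stem, role=role,
        atoms=[(el, m, *xyz) for el, m, xyz in zip(elements, masses, coords)],
        electronic_energy=float(scf[-1]),
        frequencies=freqs,
        multiplicity_levels=[(mult, 0.0)],
        rot_symmetry_number=sigma,
        charge=charge,
    )


def _parse_orientation_blocks(text: str, path: Path):
    """Extract (elements, coords) from each 'Standard orientation' table."""
    out = []
    for m in re.finditer(r"Standard orientation:", text):
        lines = text[m.end():].splitlines()
        rows = []
        dashes = 0
        for ln in lines:
            if set(ln.strip()) == {"-"} and ln.strip():
                dashes += 1
                if dashes == 3:
                    break
                continue
            if dashes == 2:
                parts = ln.split()
                if len(parts) >= 6:
                    rows.append((_SYMBOL.get(int(parts[1]), f"X{parts[1]}"),
                                 [float(parts[-3]), float(parts[-2]), float(parts[-1])]))
        if dashes < 3:
            raise ParseError(f"{path}: truncated orientation block at byte {m.start()}")
        if rows:
            out.append(([r[0] for r in rows], [r[1] for r in rows]))
    return out


_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 16: "S", 17: "Cl", 2: "He",
           10: "Ne", 18: "Ar", 15: "P", 35: "Br", 53: "I"}
_NUMBER = {v: k for k, v in _SYMBOL.items()}


# ----------------------------------------------------------------------------
# *.eif run-control dialect
# ----------------------------------------------------------------------------

_SPECIES_KEYS = ("REACT1", "REACT2", "TS", "PROD1", "PROD2", "RC", "PC")
_TORSION_KEY = re.compile(r"^(RED_MOM_INERT|TORFREQ|TORNSYM|TORBARRIER)_(\w+)$")


@dataclass
class EifConfig:
    """Parsed run-control file (key-value dialect, case-insensitive keys)."""

    method: str
    species_files: dict = field(default_factory=dict)       # role key -> path
    rxsym: Fraction | None = None
    irc_files: list = field(default_factory=list)
    pathpoints_dir: Path | None = None
    pathpoints_template: Path | None = None
    hindrot: str | None = None
    torsion_params: dict = field(default_factory=dict)      # species -> {param: value}
    temperatures: list = field(default_factory=lambda: [298.15])
    pressure: float = 1.0
    unknown_keys: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.temperatures or any(t <= 0 for t in self.temperatures):
            raise ValidationError("temperature grid must be strictly positive")
        if any(b <= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            raise ValidationError("temperature grid must be strictly increasing")


def parse_eif(path) -> EifConfig:
    """Parse a ``*.eif`` run-control file.

    Recognized keywords (case-insensitive): METHOD, REACT1/2, TS, PROD1/2,
    RC, PC, RXSYM, IRC, PATHPOINTS, PATHPOINTS_INP, HINDROT,
    RED_MOM_INERT_x / TORFREQ_x / TORNSYM_x / TORBARRIER_x, TEMPERATURE,
    PRESSURE.  Unknown keys are collected and warned about, never silently
    dropped.
    """
    path = Path(path)
    base = path.parent
    kv: list[tuple[str, str]] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        kv.append((parts[0].upper(), parts[1].strip() if len(parts) > 1 else ""))

    method = None
    cfg_kwargs: dict = {"species_files": {}, "irc_files": [],
                        "torsion_params": {}, "unknown_keys": []}
    temps = None
    for key, value in kv:
        if key == "METHOD":
            method = value.upper()
        elif key in _SPECIES_KEYS:
            cfg_kwargs["species_files"][key] = base / value
        elif key == "RXSYM":
            try:
                cfg_kwargs["rxsym"] = Fraction(value)
            except (ValueError, ZeroDivisionError) as exc:
                raise ParseError(f"{path}: RXSYM value {value!r} is not numeric") from exc
        elif key == "IRC":
            cfg_kwargs["irc_files"].extend(base / v for v in value.split())
        elif key == "PATHPOINTS":
            cfg_kwargs["pathpoints_dir"] = base / value
        elif key == "PATHPOINTS_INP":
            cfg_kwargs["pathpoints_template"] = base / value
        elif key == "HINDROT":
            hr = value.upper()
            if hr not in ("PG", "AS"):
                raise ParseError(f"{path}: HINDROT must be PG or AS, got {value!r}")
            cfg_kwargs["hindrot"] = hr
        elif key == "TEMPERATURE":
            temps = [float(v) for v in value.split()]
        elif key == "PRESSURE":
            cfg_kwargs["pressure"] = float(value)
        else:
            m = _TORSION_KEY.match(key)
            if m:
                param, species = m.groups()
                cfg_kwargs["torsion_params"].setdefault(species, {})[param] = float(value)
            else:
                cfg_kwargs["unknown_keys"].append(key)
                warnings.warn(f"{path}: unknown keyword {key!r} ignored", stacklevel=2)
    if method is None:
        raise ParseError(f"{path}: mandatory keyword METHOD missing")
    if temps is not None:
        cfg_kwargs["temperatures"] = temps
    return EifConfig(method=method, **cfg_kwargs)


# ----------------------------------------------------------------------------
# IRC profiles
# ----------------------------------------------------------------------------

@dataclass
class IRCTable:
    """Merged IRC: s (amu^1/2 bohr, ascending, contains 0) vs V (hartree,
    re-zeroed so the reactant-side reference is 0)."""

    s: np.ndarray
    V: np.ndarray
    step_size: float
    direction_note: str = ""

    def V_kcal(self) -> np.ndarray:
        return self.V * HARTREE_KCALMOL


def _read_branch(path) -> np.ndarray:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}: expected two columns (s, V), got {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ParseError(f"{path}: empty IRC file")
    arr = np.array(rows)
    ds = np.diff(arr[:, 0])
    if np.any(ds == 0):
        raise ParseError(f"{path}: duplicated s values")
    if not (np.all(ds > 0) or np.all(ds < 0)):
        raise ParseError(f"{path}: s must be monotone within a branch")
    if ds[0] < 0:
        arr = arr[::-1]
    return arr


def read_irc(paths, reactant_side: str | None = None,
             reactant_energy: float | None = None) -> IRCTable:
    """Merge IRC branch files into one table with the TS at s = 0.

    Each file holds two columns (s, V/hartree) - either a full signed path or
    one branch with s >= 0 measured from the TS.  For unsigned branch pairs
    the branch whose endpoint energy is lower is taken as reactant-side
    (``reactant_side='first'``/``'second'`` overrides the heuristic).  The
    energy zero is the reactant reference: ``reactant_energy`` (hartree, the
    sum of reactant electronic energies) when given, else the reactant-side
    endpoint.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ParseError("no IRC files given")
    branches = [_read_branch(p) for p in paths]

    if len(branches) == 1:
        arr = branches[0]
        if arr[0, 0] >= 0:   # single unsigned branch
            warnings.warn("single IRC branch: one side of the path is missing",
                          stacklevel=2)
        merged = arr
    elif len(branches) == 2:
        a, b = branches
        signed = [br for br in branches if br[0, 0] < 0]
        if len(signed) == 2:
            merged = np.vstack([a, b])
            merged = merged[np.argsort(merged[:, 0])]
        elif len(signed) == 1:
            merged = np.vstack([a, b])
            merged = merged[np.argsort(merged[:, 0])]
        else:
            # two unsigned branches from the TS outward
            if reactant_side == "first":
                r_idx = 0
            elif reactant_side == "second":
                r_idx = 1
            else:
                r_idx = 0 if a[-1, 1] < b[-1, 1] else 1
            r, p = branches[r_idx], branches[1 - r_idx]
            r = r.copy()
            r[:, 0] *= -1.0
            merged = np.vstack([r[::-1], p])
            # both branches include s=0? drop duplicate
    else:
        raise ParseError("expected one or two IRC files")

    s, V = merged[:, 0], merged[:, 1]
    keep = np.concatenate([[True], np.diff(s) > 1e-12])
    if not np.all(keep):
        dup_idx = np.where(~keep)[0]
        if np.allclose(V[dup_idx], V[dup_idx - 1], rtol=0, atol=1e-10):
            s, V = s[keep], V[keep]
        else:
            raise ParseError("IRC branches overlap in s with inconsistent energies")
    if np.any(np.diff(s) <= 0):
        raise ParseError("IRC branches overlap in s")
    if not np.any(np.isclose(s, 0.0, atol=1e-9)):
        raise ParseError("merged IRC does not contain the s = 0 (TS) point")

    if reactant_energy is not None:
        V = V - reactant_energy
        note = "re-zeroed to supplied reactant energy"
    else:
        V = V - V[0]
        note = "re-zeroed to reactant-side endpoint"
    step = float(np.median(np.diff(s)))
    return IRCTable(s=s, V=V, step_size=step, direction_note=note)


# ----------------------------------------------------------------------------
# frequency-job input emission
# ----------------------------------------------------------------------------

GEOMETRY_PLACEHOLDER = "{GEOMETRY}"


def emit_pathpoint_inputs(selection, geometries, template: str, outdir) -> list[Path]:
    """Write one frequency-job input per selected path point.

    ``selection``: s values; ``geometries``: matching list of (element, x, y, z)
    lists; ``template``: job-file text containing ``{GEOMETRY}``.  Files are
    named deterministically by signed s value.
    """
    if not selection:
        raise ValidationError("no TS-zone points selected; nothing to emit")
    if GEOMETRY_PLACEHOLDER not in template:
        raise ValidationError(
            f"template lacks the geometry placeholder {GEOMETRY_PLACEHOLDER!r}")
    if len(geometries) != len(selection):
        raise ValidationError("selection and geometry lists differ in length")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for s, geom in zip(selection, geometries):
        body = "\n".join(f"{el:2s} {x:14.8f} {y:14.8f} {z:14.8f}"
                         for el, x, y, z in geom)
        name = f"pathpoint_s{s:+.4f}.inp"
        p = outdir / name
        p.write_text(template.replace(GEOMETRY_PLACEHOLDER, body))
        written.append(p)
    return written


# ----------------------------------------------------------------------------
# rate tables
# ----------------------------------------------------------------------------

def _sig2(x: float) -> str:
    """Two-significant-figure display form, e.g. 3.4e-13."""
    if x == 0 or not math.isfinite(x):
        return str(x)
    return f"{x:.1e}"


def write_rate_table(result, path) -> Path:
    """Write a rate result as a TSV table (full precision + 2-sig-fig display).

    Columns: T, dG++(1M), k_TST, [s*, k_CVT], [kappa, k_TST*kappa,
    [k_CVT*kappa]], [branching %], then display columns.  Units in header.
    """
    path = Path(path)
    if result.temperatures.size < 1:
        raise ValidationError("rate result holds no temperatures")
    unit = result.unit
    cols = ["T/K", "dG_1M/kcal.mol^-1", f"k_TST/{unit}"]
    have_cvt = result.k_cvt is not None
    have_kappa = result.kappa_eckart is not None
    have_branch = result.branching_percent is not None
    if have_cvt:
        cols += ["s_CVT*/amu^0.5.bohr", f"k_CVT/{unit}"]
    if have_kappa:
        cols += ["kappa_Eckart", f"k_TST.kappa/{unit}"]
        if have_cvt:
            cols += [f"k_CVT.kappa/{unit}"]
    if have_branch:
        cols += ["branching/%"]
    disp = [f"k_TST({unit},2sf)"] + ([f"k_CVT({unit},2sf)"] if have_cvt else [])
    lines = ["\t".join(cols + disp)]
    for i, T in enumerate(result.temperatures):
        row = [f"{T:.4f}", f"{result.dG_1M[i]:.12e}", f"{result.k_tst[i]:.12e}"]
        if have_cvt:
            row += [f"{result.s_cvt_star[i]:+.4f}", f"{result.k_cvt[i]:.12e}"]
        if have_kappa:
            kap = result.kappa_eckart[i]
            row += [f"{kap:.12e}", f"{result.k_tst[i] * kap:.12e}"]
            if have_cvt:
                row += [f"{result.k_cvt[i] * kap:.12e}"]
        if have_branch:
            row += [f"{result.branching_percent[i]:.1f}"]
        row += [_sig2(result.k_tst[i])]
        if have_cvt:
            row += [_sig2(result.k_cvt[i])]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_rate_table(path):
    """Read back a rate table written by :func:`write_rate_table`.

    Returns (header columns, float matrix of the full-precision columns).
    """
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    n_full = len([c for c in header if "2sf" not in c])
    rows = [[float(v) for v in ln.split("\t")[:n_full]] for ln in lines[1:]]
    return header, np.array(rows)
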