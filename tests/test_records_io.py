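"""Species records, the neutral YAML schema, the vendor-log adapter, the
*.eif dialect, IRC merging, path-point emission, and rate tables."""

import warnings
from pathlib import Path

import numpy as np
import pytest
import yaml

from ratepath import chem_io
from ratepath.errors import ParseError, SchemaError, ValidationError
from ratepath.records import SpeciesRecord, TorsionSpec
from ratepath.synthetic import write_qc_log


# ---------------------------------------------------------------- records --

def test_single_atom_record_is_valid_and_degenerate():
    rec = SpeciesRecord(label="He", role="R1", atoms=[("He", 4.0026, 0, 0, 0)],
                        electronic_energy=-2.9, multiplicity_levels=[(2, 0.0)])
    assert rec.torsions == []
    assert rec.n_imaginary == 0
    assert rec.zpe_kcal() == 0.0


def test_negative_frequency_counts_as_imaginary():
    rec = SpeciesRecord(label="ts", role="TS",
                        atoms=[("O", 16.0, 0, 0, 0), ("H", 1.0, 1, 0, 0)],
                        electronic_energy=-1.0, frequencies=[-1520.3, 600.0])
    assert rec.n_imaginary == 1
    assert rec.imaginary_frequency == pytest.approx(1520.3)


@pytest.mark.parametrize("role,freqs", [
    ("TS", [600.0]),                 # TS with no imaginary mode
    ("TS", [-100.0, -200.0, 600.0]),  # TS with two
    ("GTS", [-100.0, 600.0]),        # GTS must have none
])
def test_imaginary_count_invariants(role, freqs):
    with pytest.raises(ValidationError):
        SpeciesRecord(label="x", role=role,
                      atoms=[("O", 16.0, 0, 0, 0), ("H", 1.0, 1, 0, 0)],
                      electronic_energy=0.0, frequencies=freqs,
                      s_value=0.1 if role == "GTS" else None)


def test_torsion_mode_index_may_not_hit_imaginary_mode():
    with pytest.raises(ValidationError):
        SpeciesRecord(label="ts", role="TS",
                      atoms=[("C", 12.0, 0, 0, 0), ("H", 1.0, 1, 0, 0)],
                      electronic_energy=0.0, frequencies=[-900.0, 100.0],
                      torsions=[TorsionSpec(freq_cm=100.0,
                                            reduced_moment_amu_A2=2.0,
                                            mode_index=0)])


# ------------------------------------------------------------ YAML schema --

def test_species_round_trip_is_identity(tmp_path, water_like):
    rec = water_like
    rec.torsions.append(TorsionSpec(freq_cm=300.0, reduced_moment_amu_A2=1.5,
                                    n_minima=3, symmetry_number=3))
    p = chem_io.write_species_record(rec, tmp_path / "r.yaml")
    back = chem_io.read_species_record(p)
    assert back == rec


def test_missing_mandatory_field_names_it(tmp_path):
    p = tmp_path / "bad.yaml"
    p.write_text(yaml.safe_dump({"schema": "ratepath-species-1",
                                 "label": "x", "role": "R1",
                                 "atoms": [["H", 1.0, 0, 0, 0]]}))
    with pytest.raises(SchemaError, match="electronic_energy_hartree"):
        chem_io.read_species_record(p)


# ------------------------------------------------------------- log adapter --

def test_log_round_trip_matches_ground_truth(tmp_path, water_like):
    p = write_qc_log(water_like, tmp_path / "r1.log")
    rec = chem_io.parse_qc_log(p)
    assert rec.electronic_energy == pytest.approx(water_like.electronic_energy, abs=1e-9)
    assert rec.frequencies == pytest.approx(water_like.frequencies, abs=1e-4)
    assert rec.rot_symmetry_number == water_like.rot_symmetry_number
    assert rec.masses_amu() == pytest.approx(water_like.masses_amu(), abs=1e-5)
    assert np.allclose(rec.coordinates(), water_like.coordinates(), atol=1e-6)


def test_log_last_frequency_block_wins(tmp_path, water_like, caplog):
    p = write_qc_log(water_like, tmp_path / "r1.log")
    text = p.read_text()
    stale = text.replace("Normal termination of synthetic job.", "")
    stale = stale.replace("3656.7000", "1111.0000")
    p.write_text(stale + text)
    with caplog.at_level("WARNING", logger="ratepath"):
        rec = chem_io.parse_qc_log(p)
    assert 3656.7 in [round(f, 1) for f in rec.frequencies]
    assert "last one wins" in caplog.text


def test_log_missing_symmetry_defaults_to_one(tmp_path, water_like, caplog):
    p = write_qc_log(water_like, tmp_path / "r1.log")
    p.write_text("\n".join(ln for ln in p.read_text().splitlines()
                           if "Rotational symmetry" not in ln))
    with caplog.at_level("WARNING", logger="ratepath"):
        rec = chem_io.parse_qc_log(p)
    assert rec.rot_symmetry_number == 1
    assert "defaulting sigma=1" in caplog.text


def test_truncated_log_raises_parse_error(tmp_path, water_like):
    p = write_qc_log(water_like, tmp_path / "r1.log")
    p.write_text(p.read_text()[:200])
    with pytest.raises(ParseError, match="truncated"):
        chem_io.parse_qc_log(p)


# ---------------------------------------------------------------- *.eif ----

FULL_EIF = """\
METHOD CVT
REACT1 react1.yaml
REACT2 react2.yaml
TS ts.yaml
PROD1 prod1.yaml
PROD2 prod2.yaml
RXSYM 12
IRC irc_f.dat irc_r.dat
PATHPOINTS pathpoints
PATHPOINTS_INP template.inp
HINDROT PG
RED_MOM_INERT_TS 1.8
TORFREQ_TS 54.0
TORNSYM_TS 3
TEMPERATURE 298.15 400 500
PRESSURE 1.0
"""


def test_full_keyword_set_parses_without_warning(tmp_path):
    p = tmp_path / "run.eif"
    p.write_text(FULL_EIF)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        cfg = chem_io.parse_eif(p)
    assert cfg.method == "CVT"
    assert cfg.hindrot == "PG"
    assert cfg.rxsym == 12
    assert len(cfg.irc_files) == 2
    assert cfg.torsion_params["TS"]["TORFREQ"] == 54.0
    assert cfg.temperatures == [298.15, 400.0, 500.0]
    assert cfg.unknown_keys == []


def test_eif_keys_are_case_insensitive(tmp_path):
    p = tmp_path / "run.eif"
    p.write_text("method tst\nts ts.yaml\nreact1 r1.yaml\n")
    cfg = chem_io.parse_eif(p)
    assert cfg.method == "TST"
    assert "TS" in cfg.species_files


def test_empty_eif_reports_missing_method(tmp_path):
    p = tmp_path / "empty.eif"
    p.write_text("")
    with pytest.raises(ParseError, match="METHOD"):
        chem_io.parse_eif(p)


def test_nonnumeric_rxsym_rejected(tmp_path):
    p = tmp_path / "run.eif"
    p.write_text("METHOD TST\nRXSYM twelve\n")
    with pytest.raises(ParseError, match="RXSYM"):
        chem_io.parse_eif(p)


def test_unknown_keyword_warns_and_is_collected(tmp_path):
    p = tmp_path / "run.eif"
    p.write_text("METHOD TST\nFROBNICATE yes\n")
    with pytest.warns(UserWarning, match="FROBNICATE"):
        cfg = chem_io.parse_eif(p)
    assert cfg.unknown_keys == ["FROBNICATE"]


# ------------------------------------------------------------------- IRC ---

def _write_branch(path, s, V):
    path.write_text("\n".join(f"{a:.6f} {b:.10f}" for a, b in zip(s, V)))


def test_two_unsigned_branches_merge_to_signed_path(tmp_path):
    # reactant branch ends higher? No: reactant-side endpoint is the energy
    # reference, so after merging the lower-endpoint branch is reactant-side.
    s = np.arange(0, 101) * 0.05
    f = tmp_path / "fwd.dat"
    r = tmp_path / "rev.dat"
    _write_branch(r, s, -0.002 * s**2)            # deeper: reactant side
    _write_branch(f, s, -0.001 * s**2)
    table = chem_io.read_irc([r, f])
    assert table.s.size == 201
    assert np.isclose(table.s, 0.0).any()
    assert table.s[0] < 0 < table.s[-1]
    assert np.all(np.diff(table.s) > 0)
    # the deeper branch ended up on the reactant side (s < 0)
    assert table.V[0] == pytest.approx(0.0)


def test_signed_single_file_round_trips_exactly(tmp_path):
    s = np.arange(-50, 51) * 0.05
    V = 0.01 / np.cosh(s / 0.3) ** 2
    p = tmp_path / "path.dat"
    p.write_text("\n".join(f"{a:.17g} {b:.17g}" for a, b in zip(s, V)))
    table = chem_io.read_irc([p])
    assert table.s == pytest.approx(s)
    assert table.V == pytest.approx(V - V[0], abs=1e-15)


def test_single_unsigned_branch_warns(tmp_path):
    s = np.arange(0, 51) * 0.05
    p = tmp_path / "half.dat"
    _write_branch(p, s, -0.001 * s**2)
    with pytest.warns(UserWarning, match="one side"):
        chem_io.read_irc([p])


def test_overlapping_branches_rejected(tmp_path):
    s = np.arange(-10, 11) * 0.05
    a, b = tmp_path / "a.dat", tmp_path / "b.dat"
    _write_branch(a, s, 0.001 * s)
    _write_branch(b, s + 0.25, 0.002 * (s + 0.25))
    with pytest.raises(ParseError, match="overlap"):
        chem_io.read_irc([a, b])


def test_nonmonotone_branch_rejected(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("0.0 0.0\n0.1 0.1\n0.05 0.2\n")
    with pytest.raises(ParseError, match="monotone"):
        chem_io.read_irc([p])


def test_reactant_side_override(tmp_path):
    s = np.arange(0, 101) * 0.05
    f, r = tmp_path / "f.dat", tmp_path / "r.dat"
    _write_branch(f, s, -0.002 * s**2)
    _write_branch(r, s, -0.001 * s**2)
    table = chem_io.read_irc([f, r], reactant_side="second")
    # 'second' file forced to the reactant side despite the heuristic
    assert table.V[-1] < table.V[0]


# --------------------------------------------------------- path-point jobs --

TEMPLATE = "#p freq\n\ncomment\n\n0 2\n{GEOMETRY}\n\n"
GEOM = [("O", 0.0, 0.0, 0.0), ("H", 1.0, 0.0, 0.0)]


def test_pathpoint_emission_one_file_per_point(tmp_path):
    sel = [-0.15, 0.05, 0.30]
    files = chem_io.emit_pathpoint_inputs(sel, [GEOM] * 3, TEMPLATE, tmp_path)
    assert len(files) == 3
    assert sorted(f.name for f in files) == [
        "pathpoint_s+0.0500.inp", "pathpoint_s+0.3000.inp", "pathpoint_s-0.1500.inp"]
    assert "O " in files[0].read_text()


def test_pathpoint_emission_requires_selection_and_placeholder(tmp_path):
    with pytest.raises(ValidationError, match="no TS-zone"):
        chem_io.emit_pathpoint_inputs([], [], TEMPLATE, tmp_path)
    with pytest.raises(ValidationError, match="GEOMETRY"):
        chem_io.emit_pathpoint_inputs([0.1], [GEOM], "no placeholder", tmp_path)


# ------------------------------------------------------------- rate table --

def _toy_result(molecularity, n=11):
    from ratepath.rates import RateResult
    T = np.linspace(250, 500, n)
    return RateResult(label="toy", temperatures=T, molecularity=molecularity,
                      k_tst=1e-13 * np.exp(-1500.0 / T),
                      k_cvt=0.7e-13 * np.exp(-1500.0 / T),
                      s_cvt_star=np.full(n, -0.05),
                      kappa_eckart=1.0 + 200.0 / T,
                      dG_1M=np.linspace(5, 6, n))


def test_rate_table_row_count_and_unit_headers(tmp_path):
    p = chem_io.write_rate_table(_toy_result(2), tmp_path / "t.tsv")
    header, data = chem_io.read_rate_table(p)
    assert data.shape[0] == 11
    assert any("cm^3 molecule^-1 s^-1" in c for c in header)
    p1 = chem_io.write_rate_table(_toy_result(1), tmp_path / "u.tsv")
    header1, _ = chem_io.read_rate_table(p1)
    assert any("k_TST/s^-1" == c for c in header1)


def test_rate_table_round_trip_to_twelve_digits(tmp_path):
    res = _toy_result(2)
    _, data = chem_io.read_rate_table(
        chem_io.write_rate_table(res, tmp_path / "t.tsv"))
    np.testing.assert_allclose(data[:, 2], res.k_tst, rtol=1e-12)
    np.testing.assert_allclose(data[:, 4], res.k_cvt, rtol=1e-12)
    np.testing.assert_allclose(data[:, 5], res.kappa_eckart, rtol=1e-12)
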