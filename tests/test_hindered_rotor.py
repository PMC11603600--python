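"""Hindered-rotor models: barrier relation, PG/AS partition functions and
properties, mode composition, and agreement with the eigenvalue oracle."""

import math

import numpy as np
import pytest

from ratepath.constants import C_LIGHT, H, K_B, R_KCAL
from ratepath.errors import ValidationError
from ratepath.hindered_rotor import (barrier_from_frequency, compose_vibrational,
                                     hr_thermo_as, hr_thermo_pg,
                                     q_ayala_schlegel, q_classical_harmonic,
                                     q_free_rotor, q_harmonic, q_pitzer_gwinn,
                                     torsion_oracle)
from ratepath.records import SpeciesRecord, TorsionSpec
from ratepath.statthermo import q_vibrational_HO
from ratepath.synthetic import make_torsion_case

T0 = 298.15


def _spec(nu=120.0, I=2.5, M=3, sigma=3, V0=None):
    return TorsionSpec(freq_cm=nu, reduced_moment_amu_A2=I, n_minima=M,
                       symmetry_number=sigma, barrier_kcal=V0)


# ------------------------------------------------------------ barrier Eq ---

def test_barrier_scales_with_frequency_squared_and_inverse_M_squared():
    v = barrier_from_frequency(_spec(nu=100.0))
    assert barrier_from_frequency(_spec(nu=200.0)) == pytest.approx(4 * v)
    assert barrier_from_frequency(_spec(nu=100.0, M=6, sigma=6)) == pytest.approx(v / 4)


def test_barrier_frequency_self_consistency():
    """Curvature of V0(1-cos M phi)/2 at the minimum reproduces nu_tau."""
    spec = _spec(nu=87.3, I=3.1, M=3)
    v0 = barrier_from_frequency(spec)           # kcal/mol
    from ratepath.constants import AMU, ANGSTROM, KCALMOL_J
    I_SI = spec.reduced_moment_amu_A2 * AMU * ANGSTROM**2
    # omega = sqrt(V''(0)/I) with V'' = V0 M^2 / 2
    omega = math.sqrt(v0 * KCALMOL_J * spec.n_minima**2 / (2 * I_SI))
    assert omega / (2 * math.pi * C_LIGHT) == pytest.approx(spec.freq_cm, rel=1e-10)


def test_mismatched_scan_barrier_warns():
    with pytest.warns(UserWarning, match="disagrees"):
        q_pitzer_gwinn(_spec(nu=54.0, I=1.8, V0=0.4), T0)


# -------------------------------------------------------------- free rotor --

def test_free_rotor_scalings():
    s = _spec()
    assert q_free_rotor(s, 4 * T0) / q_free_rotor(s, T0) == pytest.approx(2.0)
    s2 = _spec(sigma=6, M=3)
    assert q_free_rotor(s2, T0) / q_free_rotor(_spec(sigma=3), T0) == pytest.approx(0.5)


# ---------------------------------------------------------------- PG model --

def test_pg_free_rotor_limit_is_exact():
    """V0 = 0: q_class = q_FR, so q_PG = q_FR * q_HO / q_CHO exactly."""
    spec = _spec(V0=0.0)
    res = q_pitzer_gwinn(spec, T0)
    assert res.q_class == pytest.approx(res.q_FR, rel=1e-14)
    assert res.q_PG == pytest.approx(
        res.q_FR * q_harmonic(spec.freq_cm, T0) / q_classical_harmonic(spec.freq_cm, T0),
        rel=1e-14)


def test_pg_approaches_ho_at_high_barrier():
    """y = 50 with M = sigma and the consistent frequency: q_PG ~ q_HO."""
    V0 = 50.0 * R_KCAL * T0
    spec, _ = make_torsion_case(V0, 3.0, 3, T_grid=(T0,))
    res = q_pitzer_gwinn(spec, T0)
    assert res.y == pytest.approx(50.0, rel=1e-12)
    assert res.q_PG / res.q_HO == pytest.approx(1.0, abs=0.05)


def test_pg_bracketing_over_barrier_range():
    for y in np.linspace(0.0, 50.0, 26):
        spec, _ = make_torsion_case(max(y, 1e-3) * R_KCAL * T0, 3.0, 3, T_grid=(T0,))
        r = q_pitzer_gwinn(spec, T0)
        free_limit = r.q_FR * r.q_HO / r.q_CHO
        # interpolant property: q_PG lies between the free-rotor and HO
        # limits; at y -> 0 the classical factor e^{-y/2} I0(y/2) undershoots
        # 1 by O(y^2), hence the small slack on the lower bound
        lo = min(r.q_HO, free_limit) * (1 - 5e-3)
        hi = max(r.q_HO, free_limit) * (1 + 1e-12)
        assert lo <= r.q_PG <= hi


def test_bessel_ratio_entropy_terms_well_defined():
    from scipy.special import i0e, i1e
    for y in [0.0, 0.5, 5.0, 50.0, 700.0, 5000.0]:
        ratio = i1e(y / 2) / i0e(y / 2)
        assert 0.0 <= ratio < 1.0


# ---------------------------------------------------------------- AS model --

def test_as_reduces_to_pg_at_zero_x_and_y():
    # tiny x (huge q_FR) and tiny y: correction -> 1
    spec, _ = make_torsion_case(1e-4, 600.0, 2, T_grid=(T0,))
    res = q_ayala_schlegel(spec, T0)
    assert res.q_AS / res.q_PG == pytest.approx(1.0, abs=1e-3)


def test_as_continuous_in_temperature(methyl_torsion):
    temps = np.arange(250.0, 400.0, 0.1)
    with pytest.warns(UserWarning, match="disagrees"):
        q = np.array([q_ayala_schlegel(methyl_torsion, float(T)).q_AS
                      for T in temps])
    rel_jump = np.abs(np.diff(q) / q[:-1])
    assert rel_jump.max() < 1e-3        # no discontinuities on a 0.1 K grid
    assert np.all(np.diff(q) > 0)       # monotone in T for this torsion


def test_as_domain_clamp_warns():
    spec, _ = make_torsion_case(30.0, 3.0, 3, T_grid=(T0,))  # y ~ 50 >> domain
    with pytest.warns(UserWarning, match="fit domain"):
        q_ayala_schlegel(spec, T0)


# ----------------------------------------------- oracle agreement (sampled) --

@pytest.mark.parametrize("M", [2, 3])
@pytest.mark.parametrize("q_fr_target,y", [(2.0, 0.5), (2.0, 10.0), (8.0, 2.0),
                                           (20.0, 0.5), (20.0, 10.0)])
def test_pg_and_as_agree_with_eigenvalue_oracle(M, q_fr_target, y):
    spec = _torsion_from_xy(1.0 / q_fr_target, y, M)
    q_exact = torsion_oracle(spec, T0, n_grid=1024)
    r = q_ayala_schlegel(spec, T0)
    assert abs(r.q_PG / q_exact - 1.0) <= 0.10
    assert abs(r.q_AS / q_exact - 1.0) <= 0.03


def _torsion_from_xy(x, y, M):
    from ratepath.constants import AMU, ANGSTROM, KCALMOL_J
    q_fr = 1.0 / x
    I_SI = (q_fr * M * H) ** 2 / (8.0 * math.pi**3 * K_B * T0)
    v0 = y * R_KCAL * T0
    nu = M / (2 * math.pi * C_LIGHT) * math.sqrt(v0 * KCALMOL_J / (2 * I_SI))
    return TorsionSpec(freq_cm=nu, reduced_moment_amu_A2=I_SI / (AMU * ANGSTROM**2),
                       n_minima=M, symmetry_number=M, barrier_kcal=v0)


# ----------------------------------------------------- thermodynamic tables --

@pytest.mark.parametrize("fn", [hr_thermo_pg, hr_thermo_as])
@pytest.mark.parametrize("T", [200.0, 298.15, 500.0, 1000.0])
def test_closed_forms_match_numerical_T_derivative(fn, T):
    spec = _spec(nu=95.0, I=2.8, M=3)
    res = fn(spec, T)
    h = 1e-3 * T

    def lnq(TT):
        return math.log(fn(spec, TT).q)

    U_num = R_KCAL * T**2 * (lnq(T + h) - lnq(T - h)) / (2 * h)
    assert res.U == pytest.approx(U_num, rel=1e-5)
    # S from U and lnq; G = -RT lnq
    S_num = 1000.0 * (U_num / T) + 1000.0 * R_KCAL * lnq(T)
    assert res.S == pytest.approx(S_num, rel=1e-5)
    assert res.G == pytest.approx(-R_KCAL * T * lnq(T), rel=1e-10)
    assert res.G == pytest.approx(res.H - T * res.S / 1000.0, rel=1e-9)


def test_pg_rows_reduce_at_zero_barrier():
    """V0 = 0: I1(0)=0, I0(0)=1, so the classical row equals the free rotor
    row and the total is free-rotor + quantum-correction rows exactly."""
    res = hr_thermo_pg(_spec(V0=0.0), T0)
    for key in ("U", "S", "H", "G"):
        assert res.rows["classical"][key] == pytest.approx(
            res.rows["free_rotor"][key], rel=1e-12)
        expect = (res.rows["free_rotor"][key] + res.rows["quantum_ho"][key]
                  - res.rows["classical_ho"][key])
        assert res.rows["total"][key] == pytest.approx(expect, rel=1e-12)


# ------------------------------------------------------------- composition --

def _record_with_torsions(n_torsions):
    freqs = [-900.0, 80.0, 110.0, 500.0, 1500.0, 3000.0]
    torsions = [TorsionSpec(freq_cm=freqs[1 + i], reduced_moment_amu_A2=2.0,
                            n_minima=3, symmetry_number=3, mode_index=1 + i)
                for i in range(n_torsions)]
    return SpeciesRecord(label="ts", role="TS",
                         atoms=[("C", 12.0, 0, 0, 0), ("H", 1.0, 1, 0, 0),
                                ("H", 1.0, 0, 1, 0)],
                         electronic_energy=0.0, frequencies=freqs,
                         torsions=torsions)


def test_compose_no_torsions_equals_plain_ho():
    rec = _record_with_torsions(0)
    assert compose_vibrational(rec, T0, "HO") == pytest.approx(
        q_vibrational_HO(rec.real_frequencies, T0), rel=1e-14)


def test_compose_single_torsion_factorizes():
    rec = _record_with_torsions(1)
    q_ho = compose_vibrational(rec, T0, "HO")
    q_pg = compose_vibrational(rec, T0, "PG")
    single = q_pitzer_gwinn(rec.torsions[0], T0)
    assert q_ho / q_pg == pytest.approx(single.q_HO / single.q_PG, rel=1e-12)


def test_compose_two_torsions_is_product_of_singles():
    rec = _record_with_torsions(2)
    q2 = compose_vibrational(rec, T0, "PG")
    expected = q_vibrational_HO([500.0, 1500.0, 3000.0], T0)
    for t in rec.torsions:
        expected *= q_pitzer_gwinn(t, T0).q_PG
    assert q2 == pytest.approx(expected, rel=1e-12)


def test_compose_rejects_ambiguous_torsion_match():
    rec = _record_with_torsions(1)
    rec.torsions[0].mode_index = None
    rec.torsions[0].freq_cm = 2000.0   # matches no mode within 1 cm^-1
    with pytest.raises(ValidationError, match="unique"):
        compose_vibrational(rec, T0, "PG")


# ------------------------------------------------------------------ oracle --

def test_oracle_free_rotor_limit():
    spec, _ = make_torsion_case(1e-5, 12.0, 2, T_grid=(T0,))
    q_fr = q_free_rotor(spec, T0)
    assert q_fr > 5
    assert torsion_oracle(spec, T0) == pytest.approx(q_fr, rel=0.005)


def test_oracle_harmonic_limit():
    # deep well: anharmonic level shifts scale as (h nu / V0), so the well
    # must be deep *relative to the level spacing* for 1% agreement
    spec, _ = make_torsion_case(200.0, 20.0, 3, T_grid=(T0,))
    q_ho = q_harmonic(spec.freq_cm, T0)
    assert torsion_oracle(spec, T0) == pytest.approx(q_ho, rel=0.01)


def test_oracle_converged_on_grid_doubling(methyl_torsion):
    with pytest.warns(UserWarning, match="disagrees"):
        q1 = torsion_oracle(methyl_torsion, T0, n_grid=1024, check_convergence=True)
        q2 = torsion_oracle(methyl_torsion, T0, n_grid=2048)
    assert q1 == pytest.approx(q2, rel=1e-8)


def test_low_barrier_methyl_case_all_models_close(methyl_torsion):
    """Sub-RT barrier: PG, AS, and the exact sum agree within 10%."""
    with pytest.warns(UserWarning, match="disagrees"):
        r = q_ayala_schlegel(methyl_torsion, T0)
        q_exact = torsion_oracle(methyl_torsion, T0)
    assert r.q_PG == pytest.approx(q_exact, rel=0.10)
    assert r.q_AS == pytest.approx(q_exact, rel=0.10)
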