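"""Compare hindered-rotor treatments of a methyl-like torsion.

A -CH3-type internal rotation (three-fold, ~0.4 kcal/mol barrier — well
below RT at room temperature) is exactly the regime where the harmonic
oscillator fails.  This prints the harmonic, free-rotor, Pitzer-Gwinn and
Ayala-Schlegel partition functions against the exact eigenvalue sum.
"""

from ratepath.hindered_rotor import q_ayala_schlegel, torsion_oracle
from ratepath.synthetic import make_torsion_case

# barrier-consistent torsion: V0 = 0.4 kcal/mol, I_r = 1.8 amu A^2, M = 3
spec, _ = make_torsion_case(0.4, 1.8, 3)
print(f"torsional frequency from the barrier curvature: {spec.freq_cm:.1f} cm^-1\n")

print(f"{'T/K':>7} {'q_HO':>8} {'q_FR':>8} {'q_PG':>8} {'q_AS':>8} {'q_exact':>8}")
for T in (200.0, 298.15, 400.0, 650.0, 1000.0):
    r = q_ayala_schlegel(spec, T)
    q_ex = torsion_oracle(spec, T)
    print(f"{T:7.1f} {r.q_HO:8.3f} {r.q_FR:8.3f} {r.q_PG:8.3f} "
          f"{r.q_AS:8.3f} {q_ex:8.3f}")

print("""
The harmonic value (q_HO) drifts away from the exact sum as T grows - the
mode behaves as a nearly free rotor (q_FR) once k_B T >> V0.  Both hindered
rotor models track the exact eigenvalue sum across the whole range, the
Ayala-Schlegel correction slightly tighter than Pitzer-Gwinn.""")
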