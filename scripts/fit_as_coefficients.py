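"""Refit the Ayala-Schlegel fifth-order correction polynomials P1, P2 against
the exact torsional eigenvalue oracle and regenerate
src/ratepath/data/as_poly.json.  Run from the repository root; only needed
when the fit domain or basis changes - the shipped coefficients were produced
by this script.

Model:  q_exact / q_PG = (1 + P2(x,y) E) / (1 + P1(x,y) E),  E = exp(-y/2),
with P1, P2 total-degree-5 bivariate polynomials in x = 1/q_FR, y = V0/RT,
no constant term (so the correction -> 1 as x,y -> 0 and as y -> inf).

Linearized LSQ: (r - 1) = E*(P2 - r*P1) with r = q_exact/q_PG.
"""
import itertools
import json
import math

import numpy as np

from ratepath.constants import AMU, ANGSTROM, C_LIGHT, H, K_B, R_KCAL
from ratepath.hindered_rotor import q_pitzer_gwinn, torsion_oracle
from ratepath.records import TorsionSpec

T = 298.15
X_MAX, Y_MAX = 0.70, 14.0


def make_spec(x, y, M):
    q_fr = 1.0 / x
    I_SI = (q_fr * M * H) ** 2 / (8.0 * math.pi**3 * K_B * T)   # sigma = M
    I_amuA2 = I_SI / (AMU * ANGSTROM**2)
    v0_kcal = y * R_KCAL * T
    # Eq-20 inversion: nu = (M / 2 pi c) sqrt(V0 / (2 I))
    v0_J = v0_kcal * 4184.0 / 6.02214076e23
    nu = M / (2 * math.pi * C_LIGHT) * math.sqrt(v0_J / (2 * I_SI))
    return TorsionSpec(freq_cm=nu, reduced_moment_amu_A2=I_amuA2, n_minima=M,
                       symmetry_number=M, barrier_kcal=v0_kcal)


def ratio(x, y, M, n_grid=1025):
    spec = make_spec(x, y, M)
    q_ex = torsion_oracle(spec, T, n_grid=n_grid)
    q_pg = q_pitzer_gwinn(spec, T).q_PG
    return q_ex / q_pg


exponents = [(i, j) for i in range(6) for j in range(6) if 1 <= i + j <= 5]


def basis(x, y):
    return np.array([x**i * y**j for i, j in exponents])


# --- training grid ---
xs = np.linspace(0.02, X_MAX, 16)
ys = np.array([0.05, 0.15, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0,
               5.0, 6.0, 8.0, 10.0, 12.0, 14.0])
Ms = [2, 3]

rows, rhs, meta = [], [], []
for x, y, M in itertools.product(xs, ys, Ms):
    r = ratio(x, y, M)
    E = math.exp(-0.5 * y)
    phi = basis(x, y)
    # weight: relative-error objective -> divide by r approx 1; also weight by 1
    rows.append(np.concatenate([E * phi, -r * E * phi]))
    rhs.append(r - 1.0)
    meta.append((x, y, M, r))

A = np.array(rows)
b = np.array(rhs)
# ridge on the P1 block: the rational form is underdetermined (many (P1,P2)
# pairs fit equally well); bias toward small P1 so the denominator stays
# safely positive over the whole domain
lam = 1e-3
reg = np.zeros((len(exponents) * 2, len(exponents) * 2))
reg[len(exponents):, len(exponents):] = lam * np.eye(len(exponents))
A_aug = np.vstack([A, np.sqrt(lam) * np.hstack([np.zeros((len(exponents),) * 2),
                                                np.eye(len(exponents))]).reshape(len(exponents), -1)])
b_aug = np.concatenate([b, np.zeros(len(exponents))])
coef, *_ = np.linalg.lstsq(A_aug, b_aug, rcond=None)
n = len(exponents)
c2, c1 = coef[:n], coef[n:]

# --- validation on the acceptance-style grid ---
def predict(x, y):
    E = math.exp(-0.5 * y)
    P1 = float(basis(x, y) @ c1)
    P2 = float(basis(x, y) @ c2)
    return (1 + P2 * E) / (1 + P1 * E)

errs = []
for q_fr in np.linspace(2, 20, 10):
    for y in np.linspace(0.5, 10, 12):
        for M in Ms:
            x = 1.0 / q_fr
            r = ratio(x, y, M)
            errs.append(abs(predict(x, y) / r - 1.0))
print("q_FR in [2,20], y in [0.5,10] grid max rel err:", max(errs))

errs2 = []
for x in np.linspace(0.05, 0.6, 12):
    for y in np.linspace(0.0, 10, 11):
        for M in Ms:
            r = ratio(x, max(y, 1e-9), M)
            errs2.append(abs(predict(x, y) / r - 1.0))
print("x<=0.6 grid max rel err:", max(errs2))

# denominator positivity scan
dens = []
for x in np.linspace(0, X_MAX, 50):
    for y in np.linspace(0, Y_MAX, 60):
        E = math.exp(-0.5 * y)
        dens.append(1 + float(basis(x, y) @ c1) * E)
        dens.append(1 + float(basis(x, y) @ c2) * E)
print("min denominator:", min(dens))

out = {
    "description": "Ayala-Schlegel rational correction to the Pitzer-Gwinn "
                   "hindered-rotor partition function: "
                   "q_AS = q_PG * (1 + P2(x,y)e^{-y/2}) / (1 + P1(x,y)e^{-y/2}); "
                   "coefficients fitted to the exact periodic torsional "
                   "eigenvalue sum (plane-wave eigensolve) over the stated domain.",
    "version": 1,
    "fit_conditions": {"T_K": T, "M_sigma": Ms, "basis": "x^i y^j, 1<=i+j<=5"},
    "domain": {"x": [0.0, X_MAX], "y": [0.0, Y_MAX]},
    "P1": {"exponents": exponents, "coeffs": c1.tolist()},
    "P2": {"exponents": exponents, "coeffs": c2.tolist()},
}
with open("src/ratepath/data/as_poly.json", "w") as fh:
    json.dump(out, fh, indent=1)
print("written")
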