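# Methods

This note records the models implemented in `ratepath`, the defaults and
numerical choices, what the synthetic fixtures do and do not emulate, and
the known limitations.

## Statistical thermodynamics

Species are ideal-gas rigid rotors with harmonic (or hindered-rotor)
vibrations. Partition functions are per molecule; the translational one is
evaluated at the molecular volume k_BT/P so that
S = R(ln q + T·dlnq/dT + 1) reproduces Sackur–Tetrode exactly. Derivatives
dlnq/dT are analytic for every component (translation 3/2T at constant
volume, rotation 1/T or 3/2T, vibration from U = RT²·dlnq/dT, electronic
from the level-weighted mean energy); the test suite cross-checks each
against central finite differences at 10⁻⁶ relative.

Vibrational partition functions are **bottom-of-well referenced**
(q = e^(−u/2)/(1−e^(−u)), u = hcν/k_BT), so the zero-point energy lives
inside q. This makes the hindered-rotor substitution a clean per-mode
drop-in: q_vib = Π_nontorsional q_HO × Π_torsions q_HR.

Rotational symmetry numbers are excluded from the partition functions by
default and applied once, as the reaction symmetry factor
σ_Rx = Πσ_R/σ_TS, with σ of the generalized transition state taken equal
to σ_TS (independent of s). An explicit override (the RXSYM keyword)
replaces the computed ratio.

**Standard states.** ΔG^‡ is first formed at the working pressure (default
1 atm) and converted to the 1 M standard state via
ΔG^‡,1M = ΔG^‡,P + Δn‡·RT·ln(V_m c°), Δn‡ = 0 (unimolecular) or −1
(bimolecular), V_m = RT/P. For Δn‡ = −1 the 1 M value is *lower* by
RT·ln(24.465) = 1.894 kcal/mol at 298.15 K and is pressure-invariant; this
is the convention that makes bimolecular rate constants come out in
M⁻¹s⁻¹ directly from the exponential, and they are reported in
cm³ molecule⁻¹ s⁻¹ after multiplying by 10³/N_A. Unimolecular rates are
standard-state independent.

Physical constants are pinned to CODATA 2018 in a single table
(`ratepath.constants`, `constants_table()` prints it for audit); no other
module carries numeric constants.

## CVT and the candidate set

k_CVT is the **discrete** minimum of k_GT over the computed generalized
transition states plus the saddle point; no interpolation in s is
performed, so the reported s* is always a point for which a (projected)
frequency analysis exists. Ties are broken toward s = 0, then toward the
reactant side. Minimizing k and maximizing ΔG^‡ are equivalent and the
tests assert both give the same s* at every temperature. Because the
saddle point is always in the candidate set, k_CVT ≤ k_TST holds by
construction.

Generalized-TS records must have zero imaginary frequencies; a
reaction-coordinate-projected frequency analysis is the expected
provenance. Reactant/product complexes are carried for reporting only;
rates are always computed reactants → dividing surface (no steady-state
treatment of two-step mechanisms).

## Reaction force analysis

F = −dV/ds is evaluated by differentiating a cubic spline through the IRC
points with **not-a-knot** end conditions — IRC data are smooth and
noise-free, so no smoothing is applied, and not-a-knot keeps the derivative
exact for cubic polynomials (natural end conditions would force V'' = 0 at
the ends and corrupt the wings). A second-order central-difference mode is
retained as a cross-check. α (minimum of F at s < 0) and γ (maximum at
s > 0) are reported **at grid points**: a selected point must be an actual
IRC geometry. A force curve without the sign structure F(α) < 0 < F(γ) has
no barrier and is rejected; a branch truncated before F returns to zero is
accepted with a warning. The TS zone is α ≤ s ≤ γ excluding s = 0, and
P_CVT = 100·(zone points)/(nonstationary IRC points), reported to one
decimal.

## Hindered rotors

The torsional potential is V₀(1 − cos Mφ)/2. When V₀ is not supplied, the
curvature relation V₀ = 8π²c²ν_τ²I_r/M² provides it; a supplied
(scan-derived) barrier always wins, with a warning when the two disagree by
more than a factor of two. M defaults to σ_τ (symmetric-top torsions such
as −CH₃ dominate in practice). Torsion–mode pairing is explicit
(mode_index) or by frequency match within 1 cm⁻¹ — never by a
low-frequency heuristic.

**Pitzer–Gwinn**: q_class = q_FR·e^(−y/2)·I₀(y/2) with y = V₀/RT and
q_FR = √(8π³I_r k_BT)/(σ_τ h), multiplied by the quantum correction
q_HO/q_CHO at ν_τ. Exponentially scaled Bessel functions (`i0e`, `i1e`)
keep the expressions finite for arbitrarily large y, and I₁/I₀ ∈ [0,1)
keeps the entropy terms well-defined.

**Ayala–Schlegel**: q_AS = q_PG·(1 + P₂E)/(1 + P₁E), E = e^(−y/2), with
P₁, P₂ fifth-order bivariate polynomials in x = 1/q_FR and y with no
constant term (so the correction → 1 as x, y → 0 and as y → ∞). The
shipped coefficients (`data/as_poly.json`, regenerable with
`scripts/fit_as_coefficients.py`) were calibrated by linearized least
squares against the exact eigenvalue sum of the torsional Hamiltonian over
x ∈ [0.02, 0.70], y ∈ [0, 14], M = σ_τ ∈ {2, 3}, with a ridge penalty on
P₁ that keeps both denominators safely positive over the whole domain.
Worst-case error against the eigensolve is 0.1 % for q_FR ∈ [2, 20],
y ∈ [0.5, 10] (and ≤ 0.4 % over the full fitted domain); outside the
domain the correction is clamped with a warning. The correction factor is
treated as common to M = 2 and 3 — the residual band-structure dependence
on M is far below the quoted error.

**Thermodynamic properties** (U, S, H, G per mode; H = U for an internal
mode, G = −RT ln q, so G = H − TS holds identically) are closed forms: the
PG total assembles from the free-rotor, classical-HO, quantum-HO and
classical-hindered rows (the latter carrying the I₁/I₀ Bessel ratio), and
the AS total adds the analytic T-derivative of the correction, obtained
from the polynomial derivative coefficients with dx/dT = −x/2T,
dy/dT = −y/T. Every closed form is verified against numerical
T-differentiation of ln q at 10⁻⁵ relative over 200–1000 K.

**Exact oracle.** `torsion_oracle` solves
H = −(ħ²/2I_r)d²/dφ² + (V₀/2)(1 − cos Mφ) in a periodic plane-wave basis,
where the cosine potential is banded, via a banded eigensolve; energies are
referenced to the potential minimum, Boltzmann-summed and divided by σ_τ.
The basis size (n_grid, default 2048) is far past convergence for thermal
states (doubling changes q by < 10⁻⁸; an optional check enforces this).
It is a validation oracle, not a production method.

## Eckart tunneling

The asymmetric Eckart barrier is parametrized by the ZPE-corrected forward
and reverse barrier heights and the saddle-point imaginary frequency
(defaults: barrier heights from the saddle point, not the variational TS; a
flag isolates that choice). Transmission probabilities use the standard
dimensionless form with α_i = 2πΔV_i/(hν*); cosh combinations are
evaluated in log space so arbitrarily thick barriers stay finite, and the
d² < 0 branch (very thin barriers) falls back to cosh + cos. The Boltzmann
average runs from the reactant asymptote to ΔV₁ + 40k_BT by adaptive
quadrature at 10⁻⁸ relative tolerance, with the barrier top flagged as a
quadrature breakpoint. Limits: κ = 1 exactly at ν* = 0, κ → Wigner's
1 + (ħω/k_BT)²/24 for small ħω/k_BT, and κ decreases monotonically with T.

## Synthetic fixtures

`ratepath.synthetic` generates complete, analytically characterized
reactions: water-like reactants (an OH radical partner for bimolecular
cases), a barrier of choice shaped as sech²(s/L) or an asymmetric Eckart
function (defaults: ΔE‡ = 5 kcal/mol, L = 0.35 amu^1/2 bohr, 100 points
per side at 0.05 amu^1/2 bohr — a typical IRC discretization), and
generalized-TS records whose low-frequency modes tilt along s as
ν(1 + a·tanh(s/w)). The tilt plants an entropy-driven shift of the
Gibbs-energy maximum away from the saddle point at high temperature; the
ground truth (grid argmax of ΔG_GT, analytic inflection points) is computed
by direct summation inside the fixtures module, independent of the
production thermochemistry. Geometry, masses and electronic levels are held
fixed along the path so the ground-truth reduction (only V(s) and the
vibrational manifold vary) is exact. Fixture trees are byte-reproducible
from (spec, seed).

What the fixtures do **not** emulate: real potential-energy surfaces,
mode–path curvature coupling, anharmonic wings of the IRC, or
finite-precision vendor output. Passing the recovery tests therefore
demonstrates the correctness of the variational machinery, not the accuracy
of any electronic-structure method.

## Problem sizes

The default test and acceptance runs use 201-point IRC grids, 40-point
generalized-TS series, 60-point hindered-rotor validation grids with a
2048-function eigensolve basis, and 20 synthetic reactions at three
temperatures — sizes chosen to mirror a realistic single-reaction study
while keeping a full validation pass in seconds on one core.

## Known limitations

- Microcanonical/improved CVT, small- and large-curvature tunneling,
  multistructural or coupled multidimensional torsions, pressure-dependent
  (master-equation) kinetics, and diffusion corrections are out of scope.
- The neutral IRC profile carries (s, V) only; emitted frequency-job inputs
  are seeded with the TS geometry and the user's IRC program supplies the
  actual path geometries.
- Two-step mechanisms are computed reactants → TS; reactant complexes are
  reported, not kinetically modeled.
- Excited electronic levels are supported per species but default to the
  single stated multiplicity.
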