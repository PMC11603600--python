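# ratepath

Gas-phase rate constants from electronic-structure data: conventional and
**canonical variational transition state theory (CVT)** in the thermodynamic
formulation, automatic selection of the minimum-energy-path points that
matter via **reaction force analysis (RFA)**, one-dimensional **hindered
rotor** treatment of torsions (Pitzer–Gwinn and Ayala–Schlegel), and
**Eckart tunneling** corrections.

It is aimed at computational kineticists who have stationary-point and IRC
output from a quantum-chemistry program and want accurate thermal rate
constants — e.g. for radical hydrogen abstractions, atmospheric oxidation,
or drug-metabolism kinetics — without running a heavyweight dynamics code.

## The model

The generalized-TST rate constant at dividing-surface position *s* along the
mass-weighted reaction coordinate is computed thermodynamically,

```
k_GT(s, T) = σ_Rx · (k_B T / h) · (c°)^Δn‡ · exp(−ΔG_GT^‡,1M(s) / RT)
```

with σ-free partition functions inside ΔG (reaction symmetry enters once as
σ_Rx = Πσ_R / σ_TS) and the 1 atm → 1 M standard-state conversion
ΔG^‡,1M = ΔG^‡,1atm + Δn‡·RT·ln(V_m c°) from K_c = K_p (c°RT/P°)^(−Δn‡).
The CVT rate constant minimizes k_GT over the computed generalized
transition states plus the saddle point,

```
k_CVT(T) = min_s k_GT(s, T)   ⇔   max_s ΔG_GT^‡(s, T)
```

so k_CVT ≤ k_TST by construction; k_TST/k_CVT is the recrossing factor.
The points that need frequency analyses are found from the reaction force
F(s) = −dV/ds: its minimum α (s < 0) and maximum γ (s > 0) at the
inflection points of V(s) delimit the transition-state zone, and only IRC
points with α ≤ s ≤ γ are selected (typically 6–12 % of the path).

Torsions replace their harmonic modes by 1-D hindered-rotor partition
functions for the potential V₀(1 − cos Mφ)/2:

* Pitzer–Gwinn: `q_PG = q_FR · e^(−y/2) I₀(y/2) · q_HO/q_CHO`, y = V₀/RT;
* Ayala–Schlegel: `q_AS = q_PG · (1 + P₂ e^(−y/2)) / (1 + P₁ e^(−y/2))`,
  with P₁, P₂ fifth-order polynomials in x = 1/q_FR and y (coefficients
  calibrated against exact torsional eigenvalue sums; see
  `docs/methods.md`);
* the barrier, when not supplied from a scan, follows from the curvature
  relation V₀ = 8π²c²ν_τ²I_r/M².

Tunneling uses the asymmetric Eckart barrier fitted to ZPE-corrected
forward/reverse barrier heights and the imaginary frequency, Boltzmann
averaged by adaptive quadrature.

## Worked example

```sh
python examples/02_hindered_rotor_models.py
```

prints, for a three-fold methyl-like torsion (V₀ = 0.4 kcal/mol,
I_r = 1.8 amu Å², ν_τ = 108.6 cm⁻¹ from the curvature relation):

```
    T/K     q_HO     q_FR     q_PG     q_AS  q_exact
  200.0    1.248    2.276    1.428    1.456    1.456
  298.1    1.887    2.779    2.017    2.036    2.036
  650.0    4.150    4.103    3.527    3.536    3.535
 1000.0    6.394    5.090    4.609    4.614    4.614
```

Because the barrier is far below RT, the harmonic value q_HO is wrong by
~40 % at 1000 K, while both hindered-rotor models track the exact
eigenvalue sum (q_exact) to better than 1 %.  The other examples show the
CVT workflow on a synthetic reaction (`01`), reaction-force point selection
(`03`), and Eckart tunneling factors (`04`).

The same workflows are scriptable from a shell: `ratepath rate run.eif`
computes a rate table from a key–value run-control file (keywords METHOD,
REACT1/2, TS, PROD1/2, RXSYM, IRC, PATHPOINTS, PATHPOINTS_INP, HINDROT,
TORFREQ_x / RED_MOM_INERT_x / TORNSYM_x, TEMPERATURE, PRESSURE),
`ratepath select-points` runs the RFA selection, `ratepath hr-thermo`
tabulates hindered-rotor properties, and `ratepath fixtures` writes a fully
synthetic run tree.

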