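"""Compute CVT rate constants for a synthetic bimolecular reaction.

Builds a complete on-disk run tree (species records, IRC profile,
generalized-TS series, *.eif control file), assembles the reaction system
through the same readers the CLI uses, and prints TST vs CVT rate constants
with the variational dividing-surface position s*.
"""

import tempfile
from pathlib import Path

from ratepath.chem_io import parse_eif
from ratepath.cli import assemble_system
from ratepath.rates import compute_rates
from ratepath.synthetic import SyntheticReactionSpec, write_fixture_tree

# a 5 kcal/mol barrier whose low-frequency modes stiffen on the reactant
# side: entropy pushes the Gibbs maximum off the saddle point at high T
spec = SyntheticReactionSpec(freq_shift_amp=-0.25, seed=3)

with tempfile.TemporaryDirectory() as d:
    eif = write_fixture_tree(d, spec, temperatures=(298.15, 600.0, 1000.0))
    cfg = parse_eif(eif)
    system = assemble_system(cfg)
    res = compute_rates(system, cfg.temperatures, method="CVT", tunneling=True)

print(f"bimolecular rate constants ({res.unit}); sigma_Rx = {res.sigma_rx}")
print(f"{'T/K':>8} {'k_TST':>12} {'k_CVT':>12} {'s*':>7} {'kappa':>8} {'k_TST/k_CVT':>12}")
for i, T in enumerate(res.temperatures):
    print(f"{T:8.2f} {res.k_tst[i]:12.3e} {res.k_cvt[i]:12.3e} "
          f"{res.s_cvt_star[i]:+7.2f} {res.kappa_eckart[i]:8.3f} "
          f"{res.recrossing[i]:12.4f}")

print("""
Reading the table: at low temperature the variational dividing surface sits
at the saddle point (s* = 0) and k_CVT equals k_TST; as T grows, entropy
moves the Gibbs-energy maximum to s* < 0 and k_CVT drops below k_TST (the
recrossing factor k_TST/k_CVT > 1 measures how much conventional TST
overestimates the rate).  kappa is the Eckart tunneling factor that
multiplies either rate constant.""")
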