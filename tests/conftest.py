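import numpy as np
import pytest

from ratepath.records import SpeciesRecord, TorsionSpec
from ratepath.synthetic import SyntheticReactionSpec, make_reaction


@pytest.fixture
def methyl_torsion():
    """A -CH3-like low-barrier torsion (scan-derived barrier supplied)."""
    return TorsionSpec(freq_cm=54.0, reduced_moment_amu_A2=1.8, n_minima=3,
                       symmetry_number=3, barrier_kcal=0.4)


@pytest.fixture
def water_like():
    return SpeciesRecord(
        label="R1", role="R1",
        atoms=[("O", 15.9949, 0.0, 0.0, 0.0),
               ("H", 1.00783, 0.9572, 0.0, 0.0),
               ("H", 1.00783, -0.2400, 0.9266, 0.0)],
        electronic_energy=-76.40,
        frequencies=[1594.8, 3656.7, 3755.8],
        rot_symmetry_number=2)


@pytest.fixture(scope="session")
def standard_reaction():
    """Bimolecular synthetic reaction with an entropy-shifted Gibbs maximum."""
    spec = SyntheticReactionSpec(freq_shift_amp=-0.25, seed=3)
    system, irc, truth = make_reaction(spec, temperatures=(298.15, 600.0, 1000.0))
    return spec, system, irc, truth


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """On-disk synthetic run tree (CVT, two temperatures)."""
    d = tmp_path_factory.mktemp("tree")
    spec = SyntheticReactionSpec(seed=11)
    from ratepath.synthetic import write_fixture_tree
    eif = write_fixture_tree(d, spec, temperatures=(298.15, 400.0))
    return d, eif, spec
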