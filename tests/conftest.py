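"""Shared fixtures: every test structure is generated programmatically."""

import numpy as np
import pytest

from pepforge import (build_ideal_peptide, fine_fragment, identify_torsions,
                      read_pdb, write_pdb)
from pepforge.fixtures import synthetic_tetrapeptide


@pytest.fixture(scope="session")
def gly3():
    """Heavy-atom triglycine with free termini: 4 unlocked backbone torsions."""
    system = build_ideal_peptide("GGG")
    torsions = identify_torsions(system)
    graph = fine_fragment(system, torsions)
    return system, torsions, graph


@pytest.fixture(scope="session")
def tetrapeptide_pdb(tmp_path_factory):
    """Synthetic N-terminal tetrapeptide stand-in written to PDB."""
    path = tmp_path_factory.mktemp("pdb") / "synthetic_tetrapeptide.pdb"
    write_pdb(synthetic_tetrapeptide(), path)
    return path


@pytest.fixture(scope="session")
def half_residue_selection(tetrapeptide_pdb):
    """The 3.5-residue N-terminal selection (residue 4 backbone-only)."""
    return read_pdb(tetrapeptide_pdb, chain="A", residue_range=(1, 3.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_peptide(rng, length=3, letters="ACDEFGHIKLMNQRSTVWY"):
    seq = "".join(rng.choice(list(letters), size=length))
    torsions = {
        i: {"phi": float(rng.uniform(-170, -50)), "psi": float(rng.uniform(-60, 170))}
        for i in range(2, length + 1)
    }
    return build_ideal_peptide(seq, torsions)
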