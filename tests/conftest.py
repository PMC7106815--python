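import numpy as np
import pytest

from cavqsar.chem_graph import Atom, MolecularGraph


def carbon_path(n: int) -> MolecularGraph:
    """n-atom all-sp3-carbon linear chain."""
    return MolecularGraph(
        atoms=[Atom("C", "sp3") for _ in range(n)],
        bonds=[(i, i + 1, 1.0) for i in range(n - 1)],
    )


def carbon_star(n_leaves: int) -> MolecularGraph:
    """Hub-and-leaves sp3 carbon graph with n_leaves + 1 atoms."""
    return MolecularGraph(
        atoms=[Atom("C", "sp3") for _ in range(n_leaves + 1)],
        bonds=[(0, i, 1.0) for i in range(1, n_leaves + 1)],
    )


@pytest.fixture
def path3():
    return carbon_path(3)


@pytest.fixture
def path4():
    return carbon_path(4)


@pytest.fixture
def path5():
    return carbon_path(5)


@pytest.fixture
def star4():
    """4-atom star: hub plus three leaves."""
    return carbon_star(3)


@pytest.fixture
def benzene():
    from cavqsar.chem_graph import read_structure

    return read_structure("c1ccccc1")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
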