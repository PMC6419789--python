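import pytest

from lewisopt import build_graph, default_table, generate_synthetic


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def table_noswap():
    return default_table(swap_c0_cminus=False)


# -- named molecules -------------------------------------------------------

@pytest.fixture
def water():
    return build_graph(["O", "H", "H"], [(0, 1), (0, 2)], 0)


@pytest.fixture
def methane():
    return build_graph(["C", "H", "H", "H", "H"],
                       [(0, 1), (0, 2), (0, 3), (0, 4)], 0)


@pytest.fixture
def ethene():
    return build_graph(["C", "C", "H", "H", "H", "H"],
                       [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)], 0)


@pytest.fixture
def ethyne():
    return build_graph(["C", "C", "H", "H"], [(0, 1), (0, 2), (1, 3)], 0)


@pytest.fixture
def acetate():
    # CH3-COO^-: C0 methyl, C1 carboxyl, O2/O3 equivalent oxygens
    return build_graph(["C", "C", "O", "O", "H", "H", "H"],
                       [(0, 1), (1, 2), (1, 3), (0, 4), (0, 5), (0, 6)], -1)


@pytest.fixture
def benzene():
    bonds = [(i, (i + 1) % 6) for i in range(6)] + [(i, 6 + i) for i in range(6)]
    return build_graph(["C"] * 6 + ["H"] * 6, bonds, 0)


@pytest.fixture
def sulfate():
    return build_graph(["S", "O", "O", "O", "O"],
                       [(0, 1), (0, 2), (0, 3), (0, 4)], -2)


@pytest.fixture
def chloromethane():
    return build_graph(["C", "Cl", "H", "H", "H"],
                       [(0, 1), (0, 2), (0, 3), (0, 4)], 0)


@pytest.fixture
def hydroxide():
    return build_graph(["O", "H"], [(0, 1)], -1)


# -- synthetic suites (session-scoped: shared across tests) ---------------

@pytest.fixture(scope="session")
def suite_small():
    """Molecules small enough for the exhaustive oracle (<= 12 pair slots)."""
    return generate_synthetic(120, max_heavy_atoms=6, seed=11,
                              max_pair_slots=12)


@pytest.fixture(scope="session")
def suite_medium():
    return generate_synthetic(80, max_heavy_atoms=10, seed=23)
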